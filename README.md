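# crispr-cohort

Analysis of CRISPR-Cas systems in case-control cohorts of assembled gut
metagenomes: consensus CRISPR-array identification, per-sample summary
statistics with group comparisons, disease-marker screening among array
elements, protospacer identification with repeat-contamination filtering,
and prophage-context classification of bacterial protospacers.  A synthetic
cohort generator with machine-readable planted truth makes every stage
testable end to end without any external data.

The package is aimed at microbiome researchers who want to compare CRISPR
repertoires between patient groups (the motivating setting is gut
microbiomes of children with autism spectrum disorders versus neurotypical
controls) and at method developers who need a planted-truth harness for
CRISPR detection in fragmented metagenomic assemblies.

## The method

**Array identification.** CRISPR arrays — alternating near-identical direct
repeats R and unique spacers S₁…Sₙ, laid out as R S₁ R S₂ … Sₙ R — are
called on contigs ≥ 200 nt by two independent built-in detectors: a
CRT-style scan for short k-mers recurring at repeat+spacer periods, and a
PILER-style enumeration of exact maximal repeats chained through
spacer-length gaps.  Adapters ingest external detector output (TSV) so
real CRT/PILER-CR/CRISPRCasFinder calls can join the consensus.  A
candidate is retained only if (a) every configured detector found it
(reciprocal interval overlap ≥ 0.5), or (b) it lies within 1 kb of an
annotated *cas* locus, or (c) its direct repeat falls in a repeat cluster
shared with at least one other array.  Repeat clustering is the greedy
DNACLUST scheme at similarity 1 − editDistance/max(len) ≥ 0.8, best of
forward/reverse-complement orientation.  An array is *complete* when both
contig flanks are ≥ 200 nt.

**Cohort statistics.** Per sample: arrays per Gb of assembly, complete
arrays, cas-adjacent arrays, spacers, and spacers per complete array.
Groups are compared per sequencing series with Welch's t-test
(t = (x̄₁−x̄₂)/√(s₁²/n₁+s₂²/n₂), Welch–Satterthwaite df), preceded by
Shapiro–Wilk normality checks and confirmed by the two-sided Mann–Whitney
U test, at α = 0.05.  Series are pooled only when case-vs-case and
control-vs-control Welch tests are both non-significant for every pair in
the pooled set.

**Markers.** Repeat clusters or exact spacers (canonical orientation)
present in ≥ 2 distinct case samples and absent from all controls are
flagged; a targeted mode counts per-series/group sample presence of query
repeats, with the two *Enterocloster bolteae* direct repeats built in.

**Protospacers.** A spacer matches a target window iff the full-coverage
ungapped Hamming distance on either strand is ≤ 4.  The search is seeded
by the pigeonhole principle (one of m+1 disjoint exact chunks of length
⌊L/(m+1)⌋ must survive m mismatches), so no hit is lost relative to an
exhaustive scan.  Hits to records that also contain the source array's
repeat (same criterion) are flagged as repeat contamination and excluded
from spacer fractions, phage lists and family abundances.

**Prophage context.** Bacterial records providing protospacers to more
than 10 distinct samples are selected; each hit is called *prophage* when
it lies in a supplied prophage region or when a gene within 1 kb carries a
phage-keyword product, else *non-prophage*; positions are grouped into
single-linkage location clusters (gap ≤ 10 kb).

## Worked example

Run the full pipeline on a small simulated cohort with a planted group
effect (case density ×0.8, case spacers-per-array +2):

```python
from crispr_cohort import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(
    seed=7, out_dir="example_run",
    cohort=CohortConfig(
        n_case=4, n_control=4, series_labels=("I", "II"),
        assembly_size_per_sample=3_000_000, assembly_size_cv=0.2,
        array_density_case=0.8 * 4_000.0, array_density_control=4_000.0,
        spacers_per_array_case=9.5, spacers_per_array_control=7.5,
        repeat_mutation_rate=0.0,
        n_phage_records=6, n_bacterial_records=3,
        phage_record_length=20_000, bacterial_record_length=60_000,
        prophage_island_length=20_000, protospacer_planting_rate=0.25,
        seed=7,
    ),
)
run_pipeline(cfg)
```

or equivalently `crispr-cohort run --config cfg.yaml --seed 7 --out
example_run`.  The run plants 80 arrays, detects 160 candidates (80 per
detector), validates all 80, and writes per-sample summaries and
comparisons.  `sample_summaries.tsv` (abridged):

```
sample_id   group series  n_arrays  arrays_per_gb  spacers_per_complete_array
      A01    case      I         9        3058.67                       12.60
      A02    case     II         9        3309.17                       16.83
      C01 control      I        10        3810.34                        7.75
      C03 control      I        15        4105.34                       10.14
```

and `comparisons.tsv` for the two headline parameters:

```
                 parameter scope  mean_case  mean_control  welch_t  welch_p   mww_p  pooled
             arrays_per_gb     I  3037.2518     3957.8430  -6.1766   0.0954  0.3333   False
             arrays_per_gb    II  3249.7461     3982.3686  -6.5429   0.0344  0.3333   False
             arrays_per_gb  I+II  3143.4990     3970.1058  -8.4343   0.0002  0.0286    True
spacers_per_complete_array  I+II    14.1083        7.4018   4.5907   0.0037  0.0286    True
```

The planted directions are recovered — cases show fewer arrays per Gb and
more spacers per complete array — and the two series, which were drawn
from the same protocol here, pass the compatibility check and pool
(`scope I+II, pooled True`).  With only 2 samples per group per series the
Mann–Whitney p cannot go below 0.33; the pooled comparisons reach
significance.  Per-sample protospacer fractions land in
`protospacer_fractions.tsv` (13–28% at planting rate 0.25), and
`repeat_queries.tsv` reports the per-series *E. bolteae* repeat presence
counts (all `0/0` on random backgrounds, as expected).

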
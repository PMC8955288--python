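# Methods

This note documents the models, algorithms, parameter choices and known
limitations of crispr-cohort, in the spirit of a methods supplement.

## Scope and assumptions

The package operates on *assembled* metagenomic contigs, never reads.
Contigs shorter than 200 nt are dropped at load time, matching the
assembly filter typical of the cohorts this pipeline targets.  All
internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the I/O boundary only.  DNA is upper-case
ACGT with N permitted (N scores as a mismatch against everything except
itself in edit-distance similarity, and invalidates exact k-mer seeds).

## Array detection

Two built-in detectors provide genuinely independent evidence:

* **k-mer periodicity (`kmer`)** — exact 8-mers recurring at a distance in
  [repeat_min+spacer_min, repeat_max+spacer_max] seed a candidate.  The
  seed match is extended to a maximal exact block, further copies are
  chained left and right through spacer-length windows (best Hamming
  match to the template, tolerance max_copy_edits+2, ties to the leftmost
  offset), and repeat boundaries are then *refined by column agreement*:
  the repeat is the maximal contiguous column window in which every
  chained copy agrees, bounded by the repeat-length maximum and by
  leaving at least a minimal spacer between copies.  The refinement first
  shrinks the seed block, because a two-copy exact match can overrun the
  true boundary where just those two copies agree by chance.
* **maximal repeats (`maxrep`)** — exact repeated substrings of at least
  the minimum repeat length (19 nt) are enumerated genome-wide via 2-bit
  hashing; occurrence pairs with gaps up to twice the maximum period (so
  a mutated middle copy cannot break the chain) anchor the same
  growth/refinement core.

Shared defaults: repeat length 19–48 nt, spacer length 17–72 nt, ≥ 3
repeat copies, ≤ 3 edits between a copy and the column-majority consensus
(ties broken alphabetically), seed k = 8.  These spans cover canonical
CRISPR geometry; they are deliberately wider than the generator's planted
geometry so detection is never definitionally trivial.  Candidates on one
contig are non-overlapping and start-sorted; every reported repeat and
spacer substring occurs verbatim at its coordinates (enforced by a
self-check invariant).

Known behaviour: with 3-copy arrays on clean sequence, a flanking column
can agree across all copies by chance (probability 4^-(c-1) per column),
shifting a boundary by 1–3 nt without changing the spacer count.  With
per-copy substitutions, a mutation in an outer repeat column truncates
the refined repeat at that column; spacer counts are preserved but
boundaries may move within one repeat length.  Recovery is therefore
scored on spacer counts, with coordinates exact in the large majority of
cases.

## Consensus validation

Cross-detector candidates are grouped per contig into equivalence classes
by transitive closure of reciprocal interval overlap (≥ 0.5 of both
lengths).  A class is retained iff it contains candidates from every
configured detector, or its representative (most repeat copies, ties to
smallest start) lies within 1 kb of a cas locus on the same contig, or
its repeat consensus belongs to a repeat cluster with ≥ 2 member arrays.
The 1 kb cas window reflects typical leader-plus-spacing scale and is
configurable; cas loci are read from GFF3 gene/CDS features whose
Name/gene/product match a cas lexicon (cas1–cas14, csn/cse/csy/csm/cmr/
csf, "CRISPR-associated").  Repeat clustering is greedy: repeats sorted
by decreasing length (ties lexicographic), the first unclustered repeat
seeds a cluster and absorbs all unclustered repeats with similarity
1 − editDistance/max(len) ≥ 0.8 in the best orientation.  Clusters are
pooled cohort-wide by default (`cluster_scope="cohort"`); a "sample"
scope restricts support to same-sample members for stricter analyses.
Completeness uses flanks ≥ 200 nt on both sides (the inclusive reading
of the flank rule).

## Cohort statistics

Welch's t-test is the primary comparison; Shapiro–Wilk p-values are
recorded and a failure (p ≤ α) raises a warning flag but never blocks the
test, since the nonparametric Mann–Whitney confirmation runs regardless
(exact null distribution when both n ≤ 8 and there are no ties, normal
approximation with tie correction otherwise).  Constant-and-equal groups
are reported as t = 0, p = 1 with a degeneracy flag.  Series pooling
requires *all* pairwise case-vs-case and control-vs-control Welch tests
to be non-significant; for three series the three-way pool additionally
requires all three pairwise passes.  No multiple-testing correction is
applied to decisions; a Bonferroni-adjusted column is emitted alongside
as an extension.

## Protospacer search

Matching is ungapped, full-coverage Hamming with a 4-mismatch budget: the
local-alignment-then-extend-to-full-coverage procedure this emulates is
equivalent to scoring every full-length window, and the Hamming contract
makes the result deterministic and oracle-checkable.  Seeding uses the
pigeonhole principle — m+1 disjoint exact chunks of length ⌊L/(m+1)⌋
(capped at 31 nt, the 2-bit int64 hash limit; shorter seeds only add
candidates) — so seeded search provably equals the exhaustive scan, which
the test suite verifies on randomized instances.  Repeat exclusion
applies the same criterion to the source array's consensus repeat: any
record matching the repeat has all of that array's spacer hits flagged
(never deleted) as repeat contamination, at record-level scope.  Spacer
fractions count distinct spacers with ≥ 1 unexcluded hit over all spacers
in the sample's validated arrays.

## Prophage-context classification

Prophage regions are *inputs* (BED-like TSV), standing in for external
prophage predictors.  A hit is *prophage* if its position lies in any
region, or if a gene overlapping it or within the 1 kb neighbour window
carries a product matching the phage-keyword lexicon (phage, prophage,
capsid, tail, terminase, integrase, portal, holin, lysin, baseplate,
virion — configurable).  Records without gene annotations are decided on
regions alone and flagged low-evidence.  Record selection requires
strictly more than 10 distinct samples (group labels ignored).  Location
clusters use single-linkage with a 10 kb gap, reported but never
asserted.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: two groups
sequenced in multiple series, with per-sample assembly sizes drawn
lognormally around a target (CV 0.25 by default, mirroring the
several-fold spread of real per-subject assemblies) and contigs i.i.d.
uniform over ACGT (minimising accidental repeat structure; accidental
detections are measured, not forbidden).  Planted array counts are
deterministic — round(density × assembly_size / 1e9) per sample — so
group effects on density are realized exactly; spacer counts per array
are shifted-geometric with floor 2 (three repeat copies, the structural
minimum of a consensus-identifiable array) and configurable group means.
Repeat copies mutate by substitution only, keeping truth coordinates
exact.  Arrays are cas-adjacent with probability 0.2 (a cas1 gene
annotation is placed within the proximity window) and truncated with
probability 0.5 (planted within 200 nt of a contig end).  Default
densities (650/700 arrays per Gb) and spacer means (9.0/7.5) sit in the
range reported for gut metagenome assemblies, with the case group lower
in density and higher in spacers per array.

Targets comprise phage records (protospacers planted anywhere) and
bacterial records carrying one prophage island each; bacterial gene
annotations tile the record with phage-keyword products inside the island
and housekeeping products outside, so both branches of the prophage rule
are exercised.  Protospacers are planted per spacer at rate 0.07 by
default with an exact mismatch count drawn from weights over 0–5 —
distance-5 plants exist precisely to probe the 4-mismatch threshold.
Decoy CRISPR arrays (a sample repeat with fresh spacers) are planted in
bacterial records to exercise repeat exclusion, and
`n_offisland_protospacers` plants an exact number of bacterial
protospacers outside islands and ≥ 3 kb from island edges, for
classification tests.  Everything flows from one seeded RNG: identical
configs produce byte-identical bundles.

What the generator does **not** emulate: real genome composition (GC
skew, repeat families, tandem repeats), assembly artifacts (chimeras,
collapsed repeats), indel mutations in repeats, partial arrays split
across contigs, and taxonomic structure.  Passing recovery tests
therefore demonstrates algorithmic correctness on structurally faithful
arrays, not performance on the pathologies of real assemblies.

## Problem sizes used in tests and the acceptance script

Chosen to exercise each claim at meaningful scale: detector recovery uses
6 samples × 0.05 Gb at 600 arrays/Gb (180 planted arrays, mutation rate
0); search equivalence uses 1,000 randomized spacer/target instances plus
50 decoy constructions; statistical calibration uses 1,000 null cohorts
and 200 effect cohorts at n = 15/15, simulated at the generator's
sampling layer (sizes, counts and spacer draws identical in distribution
to the full generator, with no sequence realization); prophage
classification uses a 14-sample cohort with exactly two off-island
plants; determinism reruns the full pipeline twice on a 6-sample cohort.

## Numerical and tie-break conventions

Consensus ties break alphabetically; chaining ties to the leftmost
offset; class representatives tie to the smallest start; cluster seeding
sorts by (length desc, sequence, sample, array).  Degenerate statistical
inputs are flagged rather than raised wherever the pipeline can proceed.
Repeat similarity on unequal-length sequences falls back from Hamming to
edit distance and says so in its return value.

## Known limitations

* Array orientation, leader detection and cas subtype classification are
  out of scope; spacer canonicalization (lexicographic min of sequence
  and reverse complement) merges strands instead.
* External detector outputs are trusted only after re-validation against
  the contigs; rows that do not reconstruct are dropped with a logged
  reason rather than repaired.
* The Hamming protospacer contract will not reproduce hit lists of
  gapped local aligners on indel-containing targets.
* Exclusion scope is per target record; assembly-level grouping is
  available only when target metadata provides assembly ids.
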
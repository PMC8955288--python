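"""Synthetic metagenome cohorts with planted, machine-readable ground truth.

The generator emulates the structure of a case-control gut-metagenome
study: per-sample assembled contig sets with planted CRISPR arrays
(cas-adjacent and orphan, complete and truncated), reference phage and
bacterial records carrying planted protospacers at controlled Hamming
distances, bacterial prophage islands, and decoy CRISPR arrays inside
bacterial records that exercise the repeat-contamination exclusion.

Everything stochastic flows from one ``numpy.random.Generator`` seeded
from the config, so a config fully determines the emitted bytes.

Planted counts are deterministic: a sample with assembly size S (nt) and
group density d (arrays/Gb) receives exactly ``round(d * S / 1e9)``
arrays.  Sample-to-sample variation in assembly size (``assembly_size_cv``)
is what gives per-sample densities and spacer means their spread, as in
real cohorts where assembly sizes differ several-fold between subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import random_dna, revcomp, mutate_substitutions, mutate_exactly, hamming
from .models import GffFeature, ProphageRegion
from .io import write_fasta, write_gff3, write_tsv

PHAGE_FAMILIES = ["Siphoviridae", "Myoviridae", "Podoviridae", "Microviridae"]

PHAGE_GENE_PRODUCTS = [
    "phage integrase",
    "phage capsid protein",
    "terminase large subunit",
    "phage tail fiber protein",
    "phage portal protein",
    "holin",
]

HOUSEKEEPING_PRODUCTS = [
    "DNA gyrase subunit A",
    "30S ribosomal protein S1",
    "elongation factor Tu",
    "DNA polymerase III subunit alpha",
    "glyceraldehyde-3-phosphate dehydrogenase",
]


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Densities are arrays per Gb of assembly; spacer counts per array are
    shifted-geometric with the given group mean; repeat copies mutate by
    substitution only at ``repeat_mutation_rate`` per base per copy.
    """

    n_case: int = 54
    n_control: int = 23
    series_labels: tuple[str, ...] = ("I", "II", "III")
    assembly_size_per_sample: int = 180_000_000
    assembly_size_cv: float = 0.25
    contig_length_distribution: tuple[int, int] = (1_000, 50_000)
    array_density_case: float = 650.0
    array_density_control: float = 700.0
    spacers_per_array_case: float = 9.0
    spacers_per_array_control: float = 7.5
    repeat_length_range: tuple[int, int] = (28, 40)
    spacer_length_range: tuple[int, int] = (32, 38)
    repeat_mutation_rate: float = 0.01
    cas_adjacent_fraction: float = 0.2
    truncated_fraction: float = 0.5
    n_phage_records: int = 25
    n_bacterial_records: int = 8
    phage_record_length: int = 40_000
    bacterial_record_length: int = 120_000
    protospacer_planting_rate: float = 0.07
    protospacer_mismatch_distribution: tuple[float, ...] = (
        0.35, 0.25, 0.18, 0.12, 0.07, 0.03,
    )
    phage_target_fraction: float = 0.7
    decoy_array_in_target_rate: float = 0.25
    prophage_island_length: int = 30_000
    n_offisland_protospacers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _range_ok(r):
            return len(r) == 2 and 0 < r[0] <= r[1]

        if self.n_case < 1 or self.n_control < 1:
            raise ConfigurationError("need at least one sample per group")
        for name in ("contig_length_distribution", "repeat_length_range",
                     "spacer_length_range"):
            if not _range_ok(getattr(self, name)):
                raise ConfigurationError(f"{name} must be a non-empty (min, max) range")
        for name in ("repeat_mutation_rate", "cas_adjacent_fraction",
                     "truncated_fraction", "protospacer_planting_rate",
                     "decoy_array_in_target_rate", "phage_target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.array_density_case <= 0 or self.array_density_control <= 0:
            raise ConfigurationError("array densities must be positive")
        if self.spacers_per_array_case <= 2 or self.spacers_per_array_control <= 2:
            raise ConfigurationError(
                "mean spacers per array must exceed 2 (counts are shifted-geometric with floor 2)"
            )
        w = self.protospacer_mismatch_distribution
        if len(w) != 6 or any(x < 0 for x in w) or sum(w) <= 0:
            raise ConfigurationError(
                "protospacer_mismatch_distribution needs 6 non-negative weights (0..5 mismatches)"
            )
        if self.contig_length_distribution[0] < 200:
            raise ConfigurationError("minimum contig length is 200 nt (assembly filter)")
        if self.assembly_size_cv < 0:
            raise ConfigurationError("assembly_size_cv must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(kwargs) - known
        if unknown:
            raise ConfigurationError(f"unknown cohort config keys: {sorted(unknown)}")
        for k, v in kwargs.items():
            if isinstance(v, list):
                kwargs[k] = tuple(v)
        return cls(**kwargs)


@dataclass
class PlantedArray:
    array_id: str
    sample_id: str
    contig_id: str
    start: int
    end: int
    repeat_seq: str
    repeat_copies: list[str]
    spacer_seqs: list[str]
    cas_adjacent: bool
    left_flank: int
    right_flank: int


@dataclass
class CohortBundle:
    """In-memory cohort: sequences, annotations and machine-readable truth."""

    config: CohortConfig
    contigs: dict[str, dict[str, str]]          # sample -> contig -> seq
    cas_features: list[GffFeature]
    metadata: pd.DataFrame
    arrays: list[PlantedArray]
    targets: dict[str, str]                     # record -> seq
    target_meta: pd.DataFrame
    islands: list[ProphageRegion]
    target_genes: list[GffFeature]
    truth: pd.DataFrame                         # one row per planted feature

    def sample_ids(self) -> list[str]:
        return list(self.metadata["sample_id"])

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        (out / "samples").mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sid, contigs in self.contigs.items():
            p = out / "samples" / f"{sid}.fasta"
            write_fasta(contigs, p)
            paths[f"fasta:{sid}"] = p
        write_gff3(self.cas_features, out / "cas_loci.gff3")
        paths["cas_loci"] = out / "cas_loci.gff3"
        write_tsv(self.metadata, out / "metadata.tsv")
        paths["metadata"] = out / "metadata.tsv"
        write_fasta(self.targets, out / "targets.fasta")
        paths["targets"] = out / "targets.fasta"
        write_tsv(self.target_meta, out / "targets_meta.tsv")
        paths["targets_meta"] = out / "targets_meta.tsv"
        islands = pd.DataFrame(
            [(r.record_id, r.start, r.end, r.source) for r in self.islands],
            columns=["record_id", "start", "end", "source"],
        )
        write_tsv(islands, out / "prophage_islands.tsv")
        paths["islands"] = out / "prophage_islands.tsv"
        write_gff3(self.target_genes, out / "target_genes.gff3")
        paths["target_genes"] = out / "target_genes.gff3"
        write_tsv(self.truth, out / "truth.tsv")
        paths["truth"] = out / "truth.tsv"
        return paths


# ---------------------------------------------------------------------------
# planting primitives


def plant_array(
    contig: str,
    repeat: str,
    spacers: list[str],
    position: int,
    mutation_rate: float,
    rng: np.random.Generator,
) -> tuple[str, dict]:
    """Insert R' S1 R' S2 ... Sn R' at `position`; each R' carries
    independent per-base substitutions at `mutation_rate`.

    Returns the modified contig and a truth dict with 0-based half-open
    coordinates on the modified contig.
    """
    if len(set(spacers)) != len(spacers):
        raise GenerationError("spacers within one array must be pairwise distinct")
    if not 0 <= position <= len(contig):
        raise GenerationError("array position outside contig")
    copies = [mutate_substitutions(rng, repeat, mutation_rate) for _ in range(len(spacers) + 1)]
    parts = []
    for i, copy in enumerate(copies):
        parts.append(copy)
        if i < len(spacers):
            parts.append(spacers[i])
    inserted = "".join(parts)
    new_contig = contig[:position] + inserted + contig[position:]
    truth = {
        "array_start": position,
        "array_end": position + len(inserted),
        "repeat_seq": repeat,
        "repeat_copies": copies,
        "spacer_seqs": list(spacers),
        "left_flank": position,
        "right_flank": len(new_contig) - (position + len(inserted)),
    }
    return new_contig, truth


def plant_protospacer(
    target: str,
    spacer: str,
    n_mismatches: int,
    strand: str,
    rng: np.random.Generator,
    position: Optional[int] = None,
    region: Optional[tuple[int, int]] = None,
) -> tuple[str, int]:
    """Replace a window of `target` so that the window, read on `strand`,
    sits at Hamming distance exactly `n_mismatches` from `spacer`."""
    L = len(spacer)
    if n_mismatches > L:
        raise GenerationError("n_mismatches exceeds spacer length")
    if strand not in "+-":
        raise GenerationError("strand must be '+' or '-'")
    lo, hi = region if region is not None else (0, len(target))
    if hi - lo < L:
        raise GenerationError("target region too short for the spacer")
    if position is None:
        position = int(rng.integers(lo, hi - L + 1))
    variant = mutate_exactly(rng, spacer, n_mismatches)
    window = variant if strand == "+" else revcomp(variant)
    new_target = target[:position] + window + target[position + L:]
    # replacement may (rarely) collide with the untouched flank; re-check
    planted = new_target[position : position + L]
    check = planted if strand == "+" else revcomp(planted)
    assert hamming(check, spacer) == n_mismatches
    return new_target, position


# ---------------------------------------------------------------------------
# per-sample planning (shared by the full generator and the summary-only
# cohort simulator used for statistical calibration)


def _draw_assembly_size(cfg: CohortConfig, rng: np.random.Generator) -> int:
    m = cfg.assembly_size_per_sample
    if cfg.assembly_size_cv == 0:
        return m
    sigma = math.sqrt(math.log(1.0 + cfg.assembly_size_cv**2))
    s = rng.lognormal(mean=math.log(m) - sigma**2 / 2.0, sigma=sigma)
    return max(int(round(s)), 4 * cfg.contig_length_distribution[1])


def _n_arrays(density: float, assembly_size: int) -> int:
    return int(round(density * assembly_size / 1e9))


def _draw_spacer_counts(mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Spacer count per array: shifted geometric on {2, 3, ...} with the
    given mean.  The floor of two spacers (three repeat copies) matches the
    structural minimum of a consensus-identifiable array; planting below it
    would only measure a definitional artifact, not detector performance."""
    if n == 0:
        return np.empty(0, dtype=int)
    return 1 + rng.geometric(1.0 / (mean - 1.0), size=n)


def _contig_lengths(cfg: CohortConfig, target: int, rng: np.random.Generator) -> list[int]:
    cmin, cmax = cfg.contig_length_distribution
    lengths: list[int] = []
    total = 0
    while total < target:
        length = int(rng.integers(cmin, cmax + 1))
        if total + length > target:
            length = target - total
            if length < 200:
                break
        lengths.append(length)
        total += length
    return lengths


def _sample_labels(cfg: CohortConfig) -> list[tuple[str, str, str]]:
    """(sample_id, group, series) for every sample, cases then controls;
    series assigned round-robin within each group."""
    labels = []
    for i in range(cfg.n_case):
        labels.append((f"A{i + 1:02d}", "case", cfg.series_labels[i % len(cfg.series_labels)]))
    for i in range(cfg.n_control):
        labels.append((f"C{i + 1:02d}", "control", cfg.series_labels[i % len(cfg.series_labels)]))
    return labels


def simulate_summary_frame(cfg: CohortConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Per-sample summary parameters drawn from the generator's sampling
    layer without realizing any sequence.

    Used for statistical calibration at cohort counts that would be
    wasteful to realize base-by-base; the count and size distributions are
    identical to the full generator's.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    rows = []
    for sample_id, group, series in _sample_labels(cfg):
        size = _draw_assembly_size(cfg, rng)
        density = cfg.array_density_case if group == "case" else cfg.array_density_control
        mean_sp = cfg.spacers_per_array_case if group == "case" else cfg.spacers_per_array_control
        n_arr = _n_arrays(density, size)
        spacer_counts = _draw_spacer_counts(mean_sp, n_arr, rng)
        truncated = rng.random(n_arr) < cfg.truncated_fraction
        cas = rng.random(n_arr) < cfg.cas_adjacent_fraction
        complete = ~truncated
        gb = size / 1e9
        rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "series": series,
                "assembly_size_gb": gb,
                "n_arrays": n_arr,
                "arrays_per_gb": n_arr / gb,
                "n_complete_arrays": int(complete.sum()),
                "n_cas_adjacent": int(cas.sum()),
                "n_spacers": int(spacer_counts.sum()),
                "spacers_per_complete_array": (
                    float(spacer_counts[complete].mean()) if complete.any() else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full cohort generation


def _place_arrays_in_sample(
    cfg: CohortConfig,
    rng: np.random.Generator,
    sample_id: str,
    contig_lengths: list[int],
    n_arrays: int,
    spacer_counts: np.ndarray,
) -> tuple[dict[str, str], list[PlantedArray], list[GffFeature]]:
    """Build the sample's contigs and insert the planned arrays."""
    rmin, rmax = cfg.repeat_length_range
    smin, smax = cfg.spacer_length_range
    contig_ids = [f"{sample_id}_c{i + 1:04d}" for i in range(len(contig_lengths))]
    lengths = np.asarray(contig_lengths)

    # plan placements in original (pre-insertion) coordinates
    eligible = np.flatnonzero(lengths >= 1200)
    if n_arrays and eligible.size == 0:
        raise GenerationError("no contig long enough to host an array")
    plans: dict[int, list[tuple[int, dict]]] = {}
    for j in range(n_arrays):
        repeat_len = int(rng.integers(rmin, rmax + 1))
        repeat = random_dna(rng, repeat_len)
        n_sp = int(spacer_counts[j])
        spacers: list[str] = []
        seen: set[str] = set()
        while len(spacers) < n_sp:
            s = random_dna(rng, int(rng.integers(smin, smax + 1)))
            if s not in seen:
                seen.add(s)
                spacers.append(s)
        truncated = rng.random() < cfg.truncated_fraction
        cas_adjacent = rng.random() < cfg.cas_adjacent_fraction
        array_len = (n_sp + 1) * repeat_len + sum(len(s) for s in spacers)
        placed = False
        for _attempt in range(200):
            ci = int(rng.choice(eligible, p=lengths[eligible] / lengths[eligible].sum()))
            clen = int(lengths[ci])
            if truncated:
                flank = int(rng.integers(0, 200))
                position = flank if rng.random() < 0.5 else clen - flank
            else:
                if clen < 401:
                    continue
                position = int(rng.integers(200, clen - 200 + 1))
            taken = plans.get(ci, [])
            # separation in pre-insertion coordinates must exceed both
            # arrays' inserted lengths so splices never interleave
            if all(
                abs(position - p) >= array_len + other["array_len"] + 400
                for p, other in taken
            ):
                plans.setdefault(ci, []).append(
                    (position, {
                        "repeat": repeat,
                        "spacers": spacers,
                        "cas_adjacent": cas_adjacent,
                        "index": j,
                        "array_len": array_len,
                    })
                )
                placed = True
                break
        if not placed:
            raise GenerationError("could not place array without collision")

    contigs: dict[str, str] = {}
    arrays: list[PlantedArray] = []
    feats: list[GffFeature] = []
    for ci, clen in enumerate(contig_lengths):
        seq = random_dna(rng, clen)
        placements = sorted(plans.get(ci, []), key=lambda t: t[0])
        offset = 0
        pending: list[tuple[dict, dict]] = []
        for position, plan in placements:
            seq, truth = plant_array(
                seq, plan["repeat"], plan["spacers"], position + offset,
                cfg.repeat_mutation_rate, rng,
            )
            offset += truth["array_end"] - truth["array_start"]
            pending.append((plan, truth))
        cid = contig_ids[ci]
        contigs[cid] = seq
        for plan, truth in pending:
            arr = PlantedArray(
                array_id=f"{sample_id}_a{plan['index'] + 1:03d}",
                sample_id=sample_id,
                contig_id=cid,
                start=truth["array_start"],
                end=truth["array_end"],
                repeat_seq=truth["repeat_seq"],
                repeat_copies=truth["repeat_copies"],
                spacer_seqs=truth["spacer_seqs"],
                cas_adjacent=plan["cas_adjacent"],
                left_flank=truth["array_start"],
                right_flank=len(seq) - truth["array_end"],
            )
            arrays.append(arr)
            if plan["cas_adjacent"]:
                gap = int(rng.integers(50, 501))
                gene_len = 900
                if arr.end + gap + gene_len <= len(seq):
                    gstart = arr.end + gap
                else:
                    gstart = max(0, arr.start - gap - gene_len)
                feats.append(
                    GffFeature(
                        seqid=cid, source="sim", type="gene",
                        start=gstart, end=gstart + gene_len, strand="+",
                        attributes={
                            "ID": f"{arr.array_id}_cas",
                            "Name": "cas1",
                            "product": "CRISPR-associated protein Cas1",
                        },
                    )
                )
    arrays.sort(key=lambda a: a.array_id)
    return contigs, arrays, feats


def _interval_free(taken: list[tuple[int, int]], start: int, end: int) -> bool:
    return all(end <= s or start >= e for s, e in taken)


def generate_cohort(cfg: CohortConfig, out_dir: str | Path | None = None) -> CohortBundle:
    """Generate the full cohort bundle; optionally write it to `out_dir`."""
    rng = np.random.default_rng(cfg.seed)

    meta_rows = []
    contigs_by_sample: dict[str, dict[str, str]] = {}
    cas_features: list[GffFeature] = []
    arrays: list[PlantedArray] = []
    for sample_id, group, series in _sample_labels(cfg):
        size = _draw_assembly_size(cfg, rng)
        lengths = _contig_lengths(cfg, size, rng)
        density = cfg.array_density_case if group == "case" else cfg.array_density_control
        mean_sp = cfg.spacers_per_array_case if group == "case" else cfg.spacers_per_array_control
        n_arr = _n_arrays(density, size)
        spacer_counts = _draw_spacer_counts(mean_sp, n_arr, rng)
        contigs, sample_arrays, feats = _place_arrays_in_sample(
            cfg, rng, sample_id, lengths, n_arr, spacer_counts
        )
        contigs_by_sample[sample_id] = contigs
        arrays.extend(sample_arrays)
        cas_features.extend(feats)
        meta_rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "series": series,
                "assembly_size_nt": sum(lengths),
            }
        )
    metadata = pd.DataFrame(meta_rows)

    # --- target records -----------------------------------------------------
    targets: dict[str, str] = {}
    meta_t = []
    islands: list[ProphageRegion] = []
    target_genes: list[GffFeature] = []
    for i in range(cfg.n_phage_records):
        rid = f"P{i + 1:02d}"
        targets[rid] = random_dna(rng, cfg.phage_record_length)
        meta_t.append({"record_id": rid, "assembly_id": rid, "taxon": f"phage {rid}",
                       "family": PHAGE_FAMILIES[i % len(PHAGE_FAMILIES)], "kind": "phage"})
    for i in range(cfg.n_bacterial_records):
        rid = f"B{i + 1:02d}"
        L = cfg.bacterial_record_length
        if cfg.prophage_island_length + 20_000 > L:
            raise ConfigurationError("bacterial record too short for its prophage island")
        targets[rid] = random_dna(rng, L)
        margin = 5_000
        istart = int(rng.integers(margin, L - cfg.prophage_island_length - margin + 1))
        islands.append(ProphageRegion(rid, istart, istart + cfg.prophage_island_length, "truth"))
        meta_t.append({"record_id": rid, "assembly_id": rid, "taxon": f"bacterium {rid}",
                       "family": "", "kind": "bacterium"})
        # tile genes: phage products inside the island, housekeeping outside
        g = 0
        pos = 200
        while pos + 1200 < L:
            center = pos + 600
            in_island = istart <= center < istart + cfg.prophage_island_length
            products = PHAGE_GENE_PRODUCTS if in_island else HOUSEKEEPING_PRODUCTS
            target_genes.append(
                GffFeature(
                    seqid=rid, source="sim", type="gene",
                    start=pos, end=pos + 1200, strand="+",
                    attributes={"ID": f"{rid}_g{g + 1:04d}",
                                "product": products[g % len(products)]},
                )
            )
            g += 1
            pos += 1600
    target_meta = pd.DataFrame(meta_t)

    # --- protospacer planting ----------------------------------------------
    island_by_record = {r.record_id: (r.start, r.end) for r in islands}
    used: dict[str, list[tuple[int, int]]] = {rid: [] for rid in targets}
    phage_ids = [m["record_id"] for m in meta_t if m["kind"] == "phage"]
    bact_ids = [m["record_id"] for m in meta_t if m["kind"] == "bacterium"]
    weights = np.asarray(cfg.protospacer_mismatch_distribution, dtype=float)
    weights = weights / weights.sum()

    proto_rows = []
    protos_by_record: dict[str, list[PlantedArray]] = {}
    off_island_budget = cfg.n_offisland_protospacers
    for arr in arrays:
        for si, spacer in enumerate(arr.spacer_seqs):
            plant_off_island = False
            if off_island_budget > 0:
                plant_off_island = True
                off_island_budget -= 1
            elif rng.random() >= cfg.protospacer_planting_rate:
                continue
            n_mm = int(rng.choice(6, p=weights))
            strand = "+" if rng.random() < 0.5 else "-"
            if plant_off_island:
                rid = bact_ids[off_island_budget % len(bact_ids)] if bact_ids else None
                if rid is None:
                    raise ConfigurationError("off-island planting requires bacterial records")
                istart, iend = island_by_record[rid]
                # stay clear of island-edge phage genes (neighbour window 1 kb
                # plus one gene tile) so annotation evidence is truly absent
                clear = 3_000
                zones = []
                if istart - clear - len(spacer) > 0:
                    zones.append((0, istart - clear))
                if iend + clear + len(spacer) < len(targets[rid]):
                    zones.append((iend + clear, len(targets[rid])))
                region = zones[int(rng.integers(0, len(zones)))]
                n_mm = min(n_mm, 4)  # off-island plants must be reportable
            elif bact_ids and rng.random() >= cfg.phage_target_fraction:
                rid = bact_ids[int(rng.integers(0, len(bact_ids)))]
                region = island_by_record[rid]
            else:
                rid = phage_ids[int(rng.integers(0, len(phage_ids)))]
                region = (0, len(targets[rid]))
            pos = None
            for _try in range(100):
                cand = int(rng.integers(region[0], region[1] - len(spacer) + 1))
                if _interval_free(used[rid], cand, cand + len(spacer)):
                    pos = cand
                    break
            if pos is None:
                continue
            targets[rid], pos = plant_protospacer(
                targets[rid], spacer, n_mm, strand, rng, position=pos
            )
            used[rid].append((pos, pos + len(spacer)))
            protos_by_record.setdefault(rid, []).append(arr)
            istart_iend = island_by_record.get(rid)
            proto_rows.append(
                {
                    "feature": "protospacer",
                    "sample_id": arr.sample_id,
                    "seq_id": rid,
                    "start": pos,
                    "end": pos + len(spacer),
                    "strand": strand,
                    "mismatches": n_mm,
                    "spacer_ref": f"{arr.array_id}:{si}",
                    "in_island": bool(
                        istart_iend and istart_iend[0] <= pos < istart_iend[1]
                    ),
                }
            )

    # --- decoy CRISPR arrays inside bacterial records ------------------------
    decoy_rows = []
    for rid in bact_ids:
        if rng.random() >= cfg.decoy_array_in_target_rate:
            continue
        source_pool = protos_by_record.get(rid) or arrays
        if not source_pool:
            continue
        src = source_pool[int(rng.integers(0, len(source_pool)))]
        n_copies = 4
        spacers = [random_dna(rng, 35) for _ in range(n_copies - 1)]
        decoy = []
        for k in range(n_copies):
            decoy.append(src.repeat_seq)
            if k < n_copies - 1:
                decoy.append(spacers[k])
        decoy_seq = "".join(decoy)
        istart, iend = island_by_record[rid]
        L = len(targets[rid])
        placed = None
        for _try in range(200):
            cand = int(rng.integers(0, L - len(decoy_seq) + 1))
            if (cand + len(decoy_seq) <= istart or cand >= iend) and _interval_free(
                used[rid], cand, cand + len(decoy_seq)
            ):
                placed = cand
                break
        if placed is None:
            continue
        targets[rid] = (
            targets[rid][:placed] + decoy_seq + targets[rid][placed + len(decoy_seq):]
        )
        used[rid].append((placed, placed + len(decoy_seq)))
        decoy_rows.append(
            {
                "feature": "decoy_array",
                "sample_id": src.sample_id,
                "seq_id": rid,
                "start": placed,
                "end": placed + len(decoy_seq),
                "repeat_seq": src.repeat_seq,
                "source_array": src.array_id,
            }
        )

    # --- truth table ---------------------------------------------------------
    truth_rows = []
    for arr in arrays:
        truth_rows.append(
            {
                "feature": "array",
                "sample_id": arr.sample_id,
                "seq_id": arr.contig_id,
                "start": arr.start,
                "end": arr.end,
                "repeat_seq": arr.repeat_seq,
                "spacer_seqs": ";".join(arr.spacer_seqs),
                "cas_adjacent": arr.cas_adjacent,
                "left_flank": arr.left_flank,
                "right_flank": arr.right_flank,
                "array_id": arr.array_id,
                "n_spacers": len(arr.spacer_seqs),
            }
        )
    for r in islands:
        truth_rows.append(
            {"feature": "prophage_island", "seq_id": r.record_id,
             "start": r.start, "end": r.end}
        )
    truth_rows.extend(proto_rows)
    truth_rows.extend(decoy_rows)
    truth = pd.DataFrame(truth_rows)

    bundle = CohortBundle(
        config=cfg,
        contigs=contigs_by_sample,
        cas_features=cas_features,
        metadata=metadata,
        arrays=arrays,
        targets=targets,
        target_meta=target_meta,
        islands=islands,
        target_genes=target_genes,
        truth=truth,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
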
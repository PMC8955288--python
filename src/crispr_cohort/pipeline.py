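"""End-to-end orchestration: simulate -> detect -> validate -> stats ->
markers -> protospacers -> prophage, with a reproducibility manifest.

Each stage writes its outputs before the next starts, so a failure in
stage k leaves the outputs of stages before k intact.  All stochastic
stages draw from the single run seed; two runs with identical config and
seed produce byte-identical stage outputs (the manifest's timestamps are
the only exception and are never checksummed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import consensus as cns
from . import detect as det
from . import markers as mk
from . import prophage as pph
from . import protospacers as pts
from . import stats as st
from .io import read_bed_regions, read_fasta, read_gff3, read_tsv, write_tsv, write_gff3
from .models import GffFeature, ValidatedArray
from .simulate import CohortConfig, generate_cohort

log = logging.getLogger("crispr_cohort")

STAGES = ["simulate", "detect", "validate", "stats", "markers", "protospacers", "prophage"]

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_STAGE = 3


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "crispr_cohort_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    cohort: Optional[CohortConfig] = None
    detectors: list[str] = field(default_factory=lambda: ["kmer", "maxrep"])
    detector_params: det.DetectorParams = field(default_factory=det.DetectorParams)
    validation: cns.ValidationParams = field(default_factory=cns.ValidationParams)
    alpha: float = 0.05
    min_case: int = mk.DEFAULT_MIN_CASE
    query_repeats: Optional[dict[str, str]] = None  # id -> sequence; None = E. bolteae set
    query_max_mismatch: int = 0
    max_mismatch: int = pts.DEFAULT_MAX_MISMATCH
    min_samples: int = pph.DEFAULT_MIN_SAMPLES
    neighbour_window: int = pph.DEFAULT_NEIGHBOUR_WINDOW
    max_gap: int = pph.DEFAULT_MAX_GAP
    external_candidates: list[str] = field(default_factory=list)
    inputs: dict[str, str] = field(default_factory=dict)
    dry_run: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineConfigError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise PipelineConfigError("alpha must lie in (0, 1)")
        if self.max_mismatch < 0 or self.query_max_mismatch < 0:
            raise PipelineConfigError("mismatch budgets must be >= 0")
        if not self.detectors:
            raise PipelineConfigError("at least one detector is required")
        bad = set(self.detectors) - set(det.BUILTIN_DETECTORS) - {"external"}
        if bad:
            raise PipelineConfigError(f"unknown detectors: {sorted(bad)}")
        if "detect" not in self.stages and "validate" in self.stages \
                and not self.external_candidates and "candidates" not in self.inputs:
            raise PipelineConfigError(
                "validate requires the detect stage, external candidate files, "
                "or an inputs.candidates path"
            )
        if "simulate" not in self.stages:
            needed = {"samples_dir", "metadata"}
            if "detect" in self.stages and not needed <= set(self.inputs):
                raise PipelineConfigError(
                    f"without the simulate stage, inputs must provide {sorted(needed)}"
                )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(d.get("cohort"), dict):
            cohort = dict(d["cohort"])
            cohort.setdefault("seed", d.get("seed", 0))
            d["cohort"] = CohortConfig.from_dict(cohort)
        if isinstance(d.get("detector_params"), dict):
            p = {k: tuple(v) if isinstance(v, list) else v
                 for k, v in d["detector_params"].items()}
            d["detector_params"] = det.DetectorParams(**p)
        if isinstance(d.get("validation"), dict):
            d["validation"] = cns.ValidationParams(**d["validation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def semantic_dict(self) -> dict[str, Any]:
        """Config content that affects results (out_dir and dry_run do not)."""
        d: dict[str, Any] = {
            "seed": self.seed,
            "stages": self.stages,
            "detectors": self.detectors,
            "detector_params": vars(self.detector_params),
            "validation": vars(self.validation),
            "alpha": self.alpha,
            "min_case": self.min_case,
            "query_repeats": self.query_repeats,
            "query_max_mismatch": self.query_max_mismatch,
            "max_mismatch": self.max_mismatch,
            "min_samples": self.min_samples,
            "neighbour_window": self.neighbour_window,
            "max_gap": self.max_gap,
            "external_candidates": self.external_candidates,
            "inputs": self.inputs,
        }
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _validated_to_frame(arrays: list[ValidatedArray]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "array_id": a.array_id,
                "sample_id": a.sample_id,
                "contig_id": a.contig_id,
                "start": a.start,
                "end": a.end,
                "repeat_consensus": a.repeat_consensus,
                "spacers": ",".join(a.spacers),
                "n_copies": a.n_copies,
                "supporting_detectors": ",".join(sorted(a.supporting_detectors)),
                "support": ",".join(sorted(a.support)),
                "left_flank": a.left_flank,
                "right_flank": a.right_flank,
                "complete": a.complete,
                "cluster_id": a.cluster_id or "",
            }
            for a in arrays
        ],
        columns=["array_id", "sample_id", "contig_id", "start", "end",
                 "repeat_consensus", "spacers", "n_copies",
                 "supporting_detectors", "support", "left_flank", "right_flank",
                 "complete", "cluster_id"],
    )


def _validated_to_gff(arrays: list[ValidatedArray]) -> list[GffFeature]:
    feats = []
    for a in arrays:
        feats.append(GffFeature(a.contig_id, "crispr-cohort", "repeat_region",
                                a.start, a.end, "+",
                                {"ID": a.array_id or "", "support": ";".join(sorted(a.support))}))
        pos = a.start
        for i, copy in enumerate(a.repeat_copies):
            feats.append(GffFeature(a.contig_id, "crispr-cohort", "repeat_unit",
                                    pos, pos + len(copy), "+",
                                    {"Parent": a.array_id or ""}))
            pos += len(copy)
            if i < len(a.spacers):
                feats.append(GffFeature(a.contig_id, "crispr-cohort", "spacer",
                                        pos, pos + len(a.spacers[i]), "+",
                                        {"Parent": a.array_id or ""}))
                pos += len(a.spacers[i])
    return feats


class PipelineRun:
    """Mutable run context shared between stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.contigs: dict[str, dict[str, str]] = {}
        self.metadata: Optional[pd.DataFrame] = None
        self.cas_features: list[GffFeature] = []
        self.targets: dict[str, str] = {}
        self.target_meta: Optional[pd.DataFrame] = None
        self.islands = []
        self.target_genes: list[GffFeature] = []
        self.candidates: dict[str, dict[str, list]] = {}  # sample -> detector -> cands
        self.validated: list[ValidatedArray] = []
        self.clusters = []
        self.summaries = []
        self.hits = []
        self.manifest: dict[str, Any] = {
            "config_hash": config.config_hash(),
            "version": _version(),
            "stages": {},
            "warnings": [],
        }

    # --- input loading ----------------------------------------------------

    def load_inputs(self) -> None:
        ins = self.config.inputs
        if "samples_dir" in ins:
            for p in sorted(Path(ins["samples_dir"]).glob("*.fasta")):
                self.contigs[p.stem] = read_fasta(p, min_length=200)
        if "metadata" in ins:
            self.metadata = read_tsv(ins["metadata"])
        if "cas_gff3" in ins:
            self.cas_features = read_gff3(ins["cas_gff3"])
        if "targets_fasta" in ins:
            self.targets = read_fasta(ins["targets_fasta"])
        if "targets_meta" in ins:
            self.target_meta = read_tsv(ins["targets_meta"])
        if "islands_tsv" in ins:
            self.islands = read_bed_regions(ins["islands_tsv"])
        if "target_genes_gff3" in ins:
            self.target_genes = read_gff3(ins["target_genes_gff3"])
        if "candidates" in ins:
            # adapter-dialect TSV lets validate run standalone on candidates
            # produced earlier (or by external tools)
            all_contigs = {c: s for cs in self.contigs.values() for c, s in cs.items()}
            contig_to_sample = {c: sid for sid, cs in self.contigs.items() for c in cs}
            for cand in det.load_external_candidates(ins["candidates"], all_contigs):
                sid = contig_to_sample.get(cand.contig_id)
                if sid is not None:
                    self.candidates.setdefault(sid, {}).setdefault(
                        cand.detector_id, []
                    ).append(cand)

    # --- stages -----------------------------------------------------------

    def stage_simulate(self) -> dict[str, Any]:
        cfg = self.config.cohort or CohortConfig(seed=self.config.seed)
        bundle = generate_cohort(cfg, out_dir=self.out / "cohort")
        self.contigs = bundle.contigs
        self.metadata = bundle.metadata
        self.cas_features = bundle.cas_features
        self.targets = bundle.targets
        self.target_meta = bundle.target_meta
        self.islands = bundle.islands
        self.target_genes = bundle.target_genes
        self._bundle = bundle
        return {
            "n_samples": len(bundle.contigs),
            "n_planted_arrays": len(bundle.arrays),
            "outputs": sorted(str(p.relative_to(self.out)) for p in (self.out / "cohort").rglob("*") if p.is_file()),
        }

    def stage_detect(self) -> dict[str, Any]:
        frames = []
        for sample_id in sorted(self.contigs):
            per_detector: dict[str, list] = {}
            for d in self.config.detectors:
                if d == "external":
                    continue
                per_detector[d] = det.detect_contigs(
                    self.contigs[sample_id], d, self.config.detector_params
                )
            self.candidates[sample_id] = per_detector
            for d, cands in per_detector.items():
                f = det.candidates_to_frame(cands)
                f.insert(0, "sample_id", sample_id)
                frames.append(f)
        for path in self.config.external_candidates:
            all_contigs = {c: s for cs in self.contigs.values() for c, s in cs.items()}
            ext = det.load_external_candidates(path, all_contigs)
            for c in ext:
                sample_id = c.contig_id.split("_c")[0]
                self.candidates.setdefault(sample_id, {}).setdefault(c.detector_id, []).append(c)
            f = det.candidates_to_frame(ext)
            if len(f):
                f.insert(0, "sample_id", [c.contig_id.split("_c")[0] for c in ext])
                frames.append(f)
        table = (pd.concat(frames, ignore_index=True) if frames
                 else det.candidates_to_frame([]).assign(sample_id=[]))
        write_tsv(table, self.out / "candidates.tsv")
        return {"n_candidates": int(len(table)),
                "outputs": ["candidates.tsv"]}

    def stage_validate(self) -> dict[str, Any]:
        vp = self.config.validation
        # harvest one repeat per cross-detector candidate class, cohort-wide
        class_reps: list[tuple[str, Any]] = []
        for sample_id in sorted(self.candidates):
            class_reps.extend(
                cns.candidate_classes(self.candidates[sample_id], sample_id,
                                      vp.min_reciprocal_overlap)
            )
        repeats = [(rep.repeat_consensus, cid.split(":")[0], cid)
                   for cid, rep in class_reps]
        self.clusters = cns.cluster_repeats(repeats, vp.cluster_similarity_threshold)
        membership = {}
        for cl in self.clusters:
            for (_, _, array_ref) in cl.members:
                membership[array_ref] = cl
        cas_loci = cns.cas_loci_from_gff(self.cas_features)
        validated: list[ValidatedArray] = []
        for sample_id in sorted(self.candidates):
            contig_lengths = {c: len(s) for c, s in self.contigs[sample_id].items()}
            validated.extend(
                cns.validate(self.candidates[sample_id], cas_loci, sample_id,
                             contig_lengths, vp, membership)
            )
        self.validated = validated
        write_tsv(_validated_to_frame(validated), self.out / "validated.tsv")
        write_gff3(_validated_to_gff(validated), self.out / "validated.gff3")
        return {"n_validated": len(validated),
                "n_repeat_clusters": len(self.clusters),
                "outputs": ["validated.tsv", "validated.gff3"]}

    def stage_stats(self) -> dict[str, Any]:
        by_sample: dict[str, list[ValidatedArray]] = {}
        for a in self.validated:
            by_sample.setdefault(a.sample_id, []).append(a)
        self.summaries = []
        for row in self.metadata.itertuples(index=False):
            self.summaries.append(
                st.summarize_sample(by_sample.get(row.sample_id, []),
                                    int(row.assembly_size_nt),
                                    row.sample_id, row.group, row.series)
            )
        sdf = st.summaries_to_frame(self.summaries)
        write_tsv(sdf, self.out / "sample_summaries.tsv")
        params = [p for p in st.DEFAULT_PARAMETERS if p != "protospacer_fraction_pct"]
        comparisons = st.run_cohort_analysis(sdf, params, self.config.alpha)
        write_tsv(st.comparisons_to_frame(comparisons), self.out / "comparisons.tsv")
        return {"n_samples": len(self.summaries),
                "n_comparisons": len(comparisons),
                "outputs": ["sample_summaries.tsv", "comparisons.tsv"]}

    def stage_markers(self) -> dict[str, Any]:
        groups = dict(zip(self.metadata["sample_id"], self.metadata["group"]))
        series_of = dict(zip(self.metadata["sample_id"], self.metadata["series"]))
        vp = self.config.validation
        reports = []
        for series in sorted(set(series_of.values())):
            arrays = [a for a in self.validated if series_of.get(a.sample_id) == series]
            repeats = [(a.repeat_consensus, a.sample_id, a.array_id or "")
                       for a in arrays]
            clusters = cns.cluster_repeats(repeats, vp.cluster_similarity_threshold)
            reports.extend(
                mk.find_marker_repeat_clusters(clusters, groups,
                                               self.config.min_case, series=series)
            )
            reports.extend(
                mk.find_marker_spacers(arrays, groups, self.config.min_case,
                                       series=series)
            )
        rep_df = mk.marker_reports_to_frame(reports)
        write_tsv(rep_df[rep_df["kind"] == "repeat_cluster"], self.out / "markers_repeats.tsv")
        write_tsv(rep_df[rep_df["kind"] == "spacer"], self.out / "markers_spacers.tsv")
        queries = self.config.query_repeats
        if queries is None:
            queries = {
                f"Ebolteae_{loc}_{strain.replace(' ', '_')}": seq
                for loc, strains in mk.ENTEROCLOSTER_BOLTEAE_REPEATS.items()
                for strain, seq in strains.items()
            }
        qres = mk.query_repeat_presence(queries, self.contigs, self.metadata,
                                        self.config.query_max_mismatch)
        write_tsv(mk.query_results_to_frame(qres, self.metadata),
                  self.out / "repeat_queries.tsv")
        n_markers = int(rep_df["is_marker"].sum()) if len(rep_df) else 0
        return {"n_marker_elements": n_markers,
                "outputs": ["markers_repeats.tsv", "markers_spacers.tsv",
                            "repeat_queries.tsv"]}

    def stage_protospacers(self) -> dict[str, Any]:
        index = pts.TargetIndex(self.targets)
        mm = self.config.max_mismatch
        contaminated_cache: dict[str, set[str]] = {}
        hits = []
        for a in self.validated:
            repeat = a.repeat_consensus
            if repeat not in contaminated_cache:
                contaminated_cache[repeat] = pts.records_containing(repeat, index, mm)
            array_hits = []
            for i, spacer in enumerate(a.spacers):
                array_hits.extend(
                    pts.find_protospacers(spacer, index, mm,
                                          spacer_ref=f"{a.array_id}:{i}",
                                          sample_id=a.sample_id)
                )
            pts.apply_repeat_exclusion(array_hits, repeat, index, mm,
                                       contaminated=contaminated_cache[repeat])
            hits.extend(array_hits)
        self.hits = hits
        write_tsv(pts.hits_to_frame(hits), self.out / "protospacer_hits.tsv")

        # per-sample spacer fractions
        refs_by_sample: dict[str, list[str]] = {}
        for a in self.validated:
            refs_by_sample.setdefault(a.sample_id, []).extend(
                f"{a.array_id}:{i}" for i in range(a.n_spacers)
            )
        hits_by_sample: dict[str, list] = {}
        for h in hits:
            hits_by_sample.setdefault(h.sample_id, []).append(h)
        frac_rows = []
        for s in self.summaries:
            refs = refs_by_sample.get(s.sample_id, [])
            frac = (pts.protospacer_fraction(refs, hits_by_sample.get(s.sample_id, []))
                    if refs else float("nan"))
            s.protospacer_fraction_pct = frac
            frac_rows.append({"sample_id": s.sample_id, "group": s.group,
                              "series": s.series, "protospacer_fraction_pct": frac})
        fdf = pd.DataFrame(frac_rows)
        write_tsv(fdf, self.out / "protospacer_fractions.tsv")
        comp = st.run_cohort_analysis(
            fdf, ["protospacer_fraction_pct"], self.config.alpha,
        ) if fdf["protospacer_fraction_pct"].notna().sum() >= 4 else []
        write_tsv(st.comparisons_to_frame(comp), self.out / "comparisons_protospacers.tsv")

        groups = dict(zip(self.metadata["sample_id"], self.metadata["group"]))
        hits_by_group: dict[str, list] = {"case": [], "control": []}
        for h in hits:
            g = groups.get(h.sample_id)
            if g in hits_by_group:
                hits_by_group[g].append(h)
        plc = pts.compare_phage_lists(hits_by_group, self.target_meta)
        lists_df = pd.DataFrame(
            [
                {"set": "case", "records": ",".join(sorted(plc.list_case))},
                {"set": "control", "records": ",".join(sorted(plc.list_control))},
                {"set": "intersection", "records": ",".join(sorted(plc.intersection))},
                {"set": "multi_protospacer", "records": ",".join(sorted(plc.multi_protospacer_records))},
            ]
        )
        write_tsv(lists_df, self.out / "phage_lists.tsv")
        fam_rows = []
        for group in ("case", "control"):
            for fam, pct in sorted(plc.family_abundance_pct(group).items()):
                fam_rows.append({"group": group, "family": fam,
                                 "relative_abundance_pct": pct,
                                 "n_hits": plc.family_counts[group][fam]})
        write_tsv(pd.DataFrame(fam_rows, columns=["group", "family",
                                                  "relative_abundance_pct", "n_hits"]),
                  self.out / "family_abundance.tsv")
        self._phage_comparison = plc
        return {"n_hits": len(hits),
                "n_excluded": sum(1 for h in hits if h.excluded),
                "outputs": ["protospacer_hits.tsv", "protospacer_fractions.tsv",
                            "comparisons_protospacers.tsv", "phage_lists.tsv",
                            "family_abundance.tsv"]}

    def stage_prophage(self) -> dict[str, Any]:
        selected = pph.select_multisample_records(self.hits, self.config.min_samples)
        selected_hits = [h for h in self.hits
                         if h.target_id in set(selected) and not h.excluded]
        calls = pph.classify_record_hits(selected_hits, self.islands,
                                         self.target_genes,
                                         self.config.neighbour_window)
        write_tsv(pph.calls_to_frame(calls), self.out / "prophage_calls.tsv")
        summary = pph.prophage_summary(calls, selected, self.config.max_gap)
        write_tsv(summary, self.out / "prophage_summary.tsv")
        return {"n_selected_records": len(selected),
                "n_calls": len(calls),
                "n_non_prophage": int(sum(1 for c in calls if c.call == "non_prophage")),
                "outputs": ["prophage_calls.tsv", "prophage_summary.tsv"]}


def _version() -> str:
    from . import __version__

    return __version__


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in order; returns the manifest."""
    run = PipelineRun(config)
    run.out.mkdir(parents=True, exist_ok=True)
    if config.dry_run:
        run.manifest["planned_stages"] = [s for s in STAGES if s in config.stages]
        run.manifest["dry_run"] = True
        return run.manifest
    if "simulate" not in config.stages:
        run.load_inputs()
    stage_fns = {
        "simulate": run.stage_simulate,
        "detect": run.stage_detect,
        "validate": run.stage_validate,
        "stats": run.stage_stats,
        "markers": run.stage_markers,
        "protospacers": run.stage_protospacers,
        "prophage": run.stage_prophage,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            info = stage_fns[stage]()
        except Exception as exc:
            run.manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(run)
            raise StageError(stage, exc) from exc
        info["status"] = "ok"
        info["seconds"] = round(time.time() - t0, 3)
        checksums = {}
        for rel in info.get("outputs", []):
            p = run.out / rel
            if p.is_file():
                checksums[rel] = _sha256(p)
        info["checksums"] = checksums
        run.manifest["stages"][stage] = info
        log.info("stage %s done in %.1fs", stage, info["seconds"])
    _write_manifest(run)
    return run.manifest


def _write_manifest(run: PipelineRun) -> None:
    run.manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(run.out / "manifest.json", "w") as fh:
        json.dump(run.manifest, fh, indent=2, sort_keys=True)
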
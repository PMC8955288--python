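"""Core record types passed between pipeline stages.

All coordinates are 0-based half-open on the forward strand of the named
contig or target record; GFF3's 1-based inclusive convention is converted
at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class CandidateArray:
    """A detector's raw repeat-spacer locus call.

    Invariant: ``"".join(interleave(repeat_copies, spacers))`` equals
    ``contig[start:end]`` and ``len(spacers) == len(repeat_copies) - 1``.
    """

    contig_id: str
    start: int
    end: int
    repeat_consensus: str
    repeat_copies: list[str]
    spacers: list[str]
    detector_id: str

    @property
    def n_copies(self) -> int:
        return len(self.repeat_copies)

    def reconstruct(self) -> str:
        parts = []
        for i, copy in enumerate(self.repeat_copies):
            parts.append(copy)
            if i < len(self.spacers):
                parts.append(self.spacers[i])
        return "".join(parts)

    def check(self, contig_seq: str, max_copy_edits: int = 3) -> None:
        """Raise ValueError if the candidate violates its invariants."""
        import edlib

        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if len(self.spacers) != len(self.repeat_copies) - 1 or self.n_copies < 2:
            raise ValueError("need n spacers = n repeat copies - 1 >= 1")
        if self.reconstruct() != contig_seq[self.start : self.end]:
            raise ValueError("array text does not match contig coordinates")
        for copy in self.repeat_copies:
            d = edlib.align(copy, self.repeat_consensus, task="distance")["editDistance"]
            if d > max_copy_edits:
                raise ValueError(
                    f"repeat copy at edit distance {d} from consensus (max {max_copy_edits})"
                )


@dataclass
class ValidatedArray:
    """A candidate retained by the consensus rule, with its evidence."""

    contig_id: str
    start: int
    end: int
    repeat_consensus: str
    repeat_copies: list[str]
    spacers: list[str]
    detector_id: str
    sample_id: str
    supporting_detectors: frozenset[str]
    support: frozenset[str]  # subset of {all_detectors, cas_adjacent, repeat_cluster}
    left_flank: int
    right_flank: int
    complete: bool
    cluster_id: Optional[str] = None
    array_id: Optional[str] = None

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    @property
    def n_copies(self) -> int:
        return len(self.repeat_copies)


@dataclass
class RepeatCluster:
    """Greedy similarity cluster of direct repeats.

    members are (repeat sequence, sample_id, array reference) tuples; every
    member is within `similarity_threshold` of `seed_repeat` in the best of
    the two orientations.
    """

    cluster_id: str
    seed_repeat: str
    members: list[tuple[str, str, str]]
    similarity_threshold: float

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_samples(self) -> set[str]:
        return {m[1] for m in self.members}

    def member_arrays(self) -> set[str]:
        return {m[2] for m in self.members}


@dataclass
class CasLocus:
    contig_id: str
    start: int
    end: int
    gene_names: list[str]


@dataclass
class ProtospacerHit:
    """One spacer-to-target window match (full coverage, ungapped)."""

    spacer_ref: str  # "sample:array:index" or caller-defined
    target_id: str
    strand: str  # "+" or "-"
    position: int  # window start, forward coordinates of the target
    mismatches: int
    length: int
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    sample_id: Optional[str] = None
    target_family: Optional[str] = None
    target_kind: Optional[str] = None


@dataclass
class SampleSummary:
    sample_id: str
    group: str
    series: str
    assembly_size_gb: float
    n_arrays: int
    arrays_per_gb: float
    n_complete_arrays: int
    n_cas_adjacent: int
    n_spacers: int
    spacers_per_complete_array: float  # nan when no complete arrays
    protospacer_fraction_pct: Optional[float] = None


@dataclass
class GroupComparison:
    parameter: str
    scope: str  # series label or "+"-joined combination
    n_case: int
    n_control: int
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    shapiro_p_case: float
    shapiro_p_control: float
    welch_t: float
    welch_p: float
    mww_u: float
    mww_p: float
    alpha: float
    degenerate: bool = False
    normality_warning: bool = False
    pooled: bool = False


@dataclass
class MarkerReport:
    kind: str  # "repeat_cluster" or "spacer"
    element_id: str
    sequence: str
    case_samples: list[str]
    control_samples: list[str]
    is_marker: bool
    series: Optional[str] = None


@dataclass
class RepeatQueryResult:
    query_id: str
    sequence: str
    counts: dict[tuple[str, str], int]  # (series, group) -> n samples with >=1 match
    matched_samples: list[str]


@dataclass
class ProphageRegion:
    record_id: str
    start: int
    end: int
    source: str = "truth"


@dataclass
class ContextCall:
    hit: ProtospacerHit
    call: str  # "prophage" or "non_prophage"
    evidence: frozenset[str]  # subset of {in_region, phage_gene_annotation}
    nearest_gene: Optional[tuple[str, str, int]] = None  # (id, product, distance nt)
    low_evidence: bool = False


@dataclass
class GffFeature:
    """Internal GFF3 feature (coordinates already 0-based half-open)."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)
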
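"""Disease-marker search among CRISPR elements.

Two marker definitions are screened per series: direct-repeat clusters and
exact spacer sequences that occur in at least `min_case` distinct case
samples and in no control sample.  A targeted mode counts, per series and
group, the samples whose contigs contain a user-supplied repeat (default:
identical match on either strand), as done for the two *Enterocloster
bolteae* direct repeats.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import edlib
import pandas as pd

from ._seq import hamming, revcomp
from .models import MarkerReport, RepeatCluster, RepeatQueryResult, ValidatedArray
from .protospacers import TargetIndex

# Direct repeats of the two CRISPR arrays of Enterocloster bolteae
# (strains ATCC BAA-613 and CBBP-2), keyed by their position relative to
# the cas locus.  The two strains' copies of the cas-adjacent repeat
# differ by a single nucleotide (in reverse-complement orientation); the
# distal repeats are identical.
ENTEROCLOSTER_BOLTEAE_REPEATS: dict[str, dict[str, str]] = {
    "cas_adjacent": {
        "ATCC BAA-613": "GTCTCCGTCCTCGCGGGCGGAGTGGGTTGAAAT",
        "CBBP-2": "ATTTCAACCCACTCCGCCCACGAGGACGGAGAC",
    },
    "distal": {
        "ATCC BAA-613": "ATTTCAATCCACAAGGCTCTCGCGAGCCTCGAC",
        "CBBP-2": "GTCGAGGCTCGCGAGAGCCTTGTGGATTGAAAT",
    },
}

DEFAULT_MIN_CASE = 2


def _is_marker(case_samples: set[str], control_samples: set[str], min_case: int) -> bool:
    return len(case_samples) >= min_case and len(control_samples) == 0


def find_marker_repeat_clusters(
    clusters: Sequence[RepeatCluster],
    groups: Mapping[str, str],
    min_case: int = DEFAULT_MIN_CASE,
    series: str | None = None,
) -> list[MarkerReport]:
    """One report per cluster; `groups` maps sample_id -> group.  Counting
    is by distinct sample (two arrays from one sample count once)."""
    out = []
    for cl in clusters:
        case = {s for (_, s, _) in cl.members if groups.get(s) == "case"}
        control = {s for (_, s, _) in cl.members if groups.get(s) == "control"}
        out.append(
            MarkerReport(
                kind="repeat_cluster",
                element_id=cl.cluster_id,
                sequence=cl.seed_repeat,
                case_samples=sorted(case),
                control_samples=sorted(control),
                is_marker=_is_marker(case, control, min_case),
                series=series,
            )
        )
    return out


def canonical_spacer(seq: str) -> str:
    """Strand-insensitive spacer key: lexicographic minimum of the sequence
    and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def find_marker_spacers(
    arrays: Sequence[ValidatedArray],
    groups: Mapping[str, str],
    min_case: int = DEFAULT_MIN_CASE,
    series: str | None = None,
) -> list[MarkerReport]:
    """Group spacers by exact sequence identity in canonical orientation and
    apply the marker rule (>= min_case distinct case samples, no controls)."""
    by_seq: dict[str, tuple[set[str], set[str]]] = {}
    for arr in arrays:
        for sp in arr.spacers:
            key = canonical_spacer(sp)
            case, control = by_seq.setdefault(key, (set(), set()))
            g = groups.get(arr.sample_id)
            if g == "case":
                case.add(arr.sample_id)
            elif g == "control":
                control.add(arr.sample_id)
    out = []
    for i, (seq, (case, control)) in enumerate(sorted(by_seq.items())):
        out.append(
            MarkerReport(
                kind="spacer",
                element_id=f"SP{i + 1:05d}",
                sequence=seq,
                case_samples=sorted(case),
                control_samples=sorted(control),
                is_marker=_is_marker(case, control, min_case),
                series=series,
            )
        )
    return out


def compare_repeats(a: str, b: str) -> tuple[str, int, bool]:
    """Orientation minimizing the distance between two repeats.

    Equal lengths compare by Hamming distance; unequal lengths fall back to
    edit distance and set the flag in the third slot.  Returns
    (orientation, distance, used_edit_distance) with orientation in
    {"forward", "revcomp"}; ties prefer forward.
    """
    if not a or not b:
        raise ValueError("empty repeat sequence")
    a, b = a.upper(), b.upper()
    if len(a) == len(b):
        d_f = hamming(a, b)
        d_r = hamming(a, revcomp(b))
        return ("forward", d_f, False) if d_f <= d_r else ("revcomp", d_r, False)
    d_f = edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    d_r = edlib.align(a, revcomp(b), task="distance", mode="NW")["editDistance"]
    return ("forward", d_f, True) if d_f <= d_r else ("revcomp", d_r, True)


def query_repeat_presence(
    queries: Mapping[str, str],
    sample_contigs: Mapping[str, Mapping[str, str]],
    metadata: pd.DataFrame,
    max_mismatch: int = 0,
) -> list[RepeatQueryResult]:
    """Count, per series and group, the samples containing each query.

    A sample matches iff any of its contigs has a window on either strand
    within `max_mismatch` Hamming distance of the query (default 0 =
    identical).  Counting is per sample; matching either strand or either
    repeat variant marks the sample once.
    """
    labels = metadata.set_index("sample_id")[["series", "group"]]
    out = []
    matched: dict[str, set[str]] = {qid: set() for qid in queries}
    for sample_id, contigs in sample_contigs.items():
        if max_mismatch == 0:
            # exact substring scan, both strands
            for qid, q in queries.items():
                rc = revcomp(q)
                for seq in contigs.values():
                    if q in seq or rc in seq:
                        matched[qid].add(sample_id)
                        break
        else:
            index = TargetIndex(contigs)
            for qid, q in queries.items():
                if index.search(q, max_mismatch):
                    matched[qid].add(sample_id)
    for qid, q in queries.items():
        counts: dict[tuple[str, str], int] = {}
        for sample_id in matched[qid]:
            if sample_id not in labels.index:
                continue
            key = (labels.loc[sample_id, "series"], labels.loc[sample_id, "group"])
            counts[key] = counts.get(key, 0) + 1
        out.append(
            RepeatQueryResult(
                query_id=qid,
                sequence=q,
                counts=counts,
                matched_samples=sorted(matched[qid]),
            )
        )
    return out


def marker_reports_to_frame(reports: Sequence[MarkerReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kind": r.kind,
                "element_id": r.element_id,
                "sequence": r.sequence,
                "series": r.series or "",
                "n_case_samples": len(r.case_samples),
                "n_control_samples": len(r.control_samples),
                "case_samples": ",".join(r.case_samples),
                "control_samples": ",".join(r.control_samples),
                "is_marker": r.is_marker,
            }
            for r in reports
        ]
    )


def query_results_to_frame(results: Sequence[RepeatQueryResult],
                           metadata: pd.DataFrame) -> pd.DataFrame:
    """Table shaped like a per-series presence count: one row per query,
    one 'case/control' column per series."""
    series_labels = sorted(metadata["series"].unique())
    rows = []
    for r in results:
        row: dict[str, object] = {"query_id": r.query_id, "sequence": r.sequence}
        for s in series_labels:
            n_case = r.counts.get((s, "case"), 0)
            n_control = r.counts.get((s, "control"), 0)
            row[f"series_{s}"] = f"{n_case}/{n_control}"
        rows.append(row)
    return pd.DataFrame(rows)
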
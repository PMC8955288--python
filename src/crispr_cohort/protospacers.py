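"""Protospacer identification: full-coverage ungapped spacer matching.

A spacer of length L matches a target window iff the Hamming distance on
one of the strands is at most `max_mismatch` (default 4); gaps are never
allowed and the window always covers the whole spacer.  The search is
seeded by the pigeonhole principle: any window within m mismatches shares
at least one of m+1 disjoint exact seed chunks of length floor(L/(m+1))
with the spacer, so exact seed lookup followed by full-window verification
loses no hits.

Hits whose target record also contains the source array's direct repeat
(same criterion) are flagged as repeat contamination - likely a CRISPR
array in the target rather than a protospacer - and never contribute to
fractions or phage lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, revcomp
from .models import ProtospacerHit

DEFAULT_MAX_MISMATCH = 4


class TargetIndex:
    """Exact seed index over a set of target records.

    Records are concatenated with single-N sentinels; seed hash tables are
    built lazily per seed length and shared across queries.
    """

    def __init__(self, records: Mapping[str, str]):
        self.record_ids = list(records)
        parts = []
        starts = []
        pos = 0
        for rid in self.record_ids:
            starts.append(pos)
            parts.append(encode(records[rid]))
            pos += len(records[rid]) + 1
            parts.append(np.array([4], dtype=np.uint8))  # sentinel
        self.codes = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.lengths = np.asarray([len(records[r]) for r in self.record_ids], np.int64)
        self._seed_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _seed_table(self, s: int) -> tuple[np.ndarray, np.ndarray]:
        if s not in self._seed_cache:
            from ._seq import kmer_hashes

            h = kmer_hashes(self.codes, s)
            idx = np.flatnonzero(h >= 0)
            hv = h[idx]
            order = np.argsort(hv, kind="stable")
            self._seed_cache[s] = (hv[order], idx[order])
        return self._seed_cache[s]

    def _exact_hash(self, chunk: np.ndarray) -> int:
        h = 0
        for c in chunk:
            h = (h << 2) | int(c)
        return h

    def _candidate_starts(self, qcodes: np.ndarray, m: int) -> np.ndarray:
        L = qcodes.size
        # floor(L/(m+1)) guarantees one exact chunk by pigeonhole; shorter
        # seeds stay sound (they only add candidates) and 31 is the 2-bit
        # int64 hash limit
        s = min(max(L // (m + 1), 1), 31)
        hashes, positions = self._seed_table(s)
        cands: list[np.ndarray] = []
        for i in range(m + 1):
            chunk = qcodes[i * s : (i + 1) * s]
            if chunk.size < s:
                break
            hv = self._exact_hash(chunk)
            lo = np.searchsorted(hashes, hv, side="left")
            hi = np.searchsorted(hashes, hv, side="right")
            if hi > lo:
                cands.append(positions[lo:hi] - i * s)
        if not cands:
            return np.empty(0, np.int64)
        t = np.unique(np.concatenate(cands))
        t = t[(t >= 0) & (t + L <= self.codes.size)]
        return t

    def _verify(self, qcodes: np.ndarray, t: np.ndarray, m: int):
        """Filter candidate global starts by full-window Hamming distance."""
        if t.size == 0:
            return t, np.empty(0, np.int64)
        L = qcodes.size
        windows = self.codes[t[:, None] + np.arange(L)[None, :]]
        mism = np.count_nonzero(windows != qcodes[None, :], axis=1)
        # sentinel codes (4) always mismatch, so cross-record windows are
        # penalised; drop them explicitly anyway
        rec = np.searchsorted(self.starts, t, side="right") - 1
        inside = (t - self.starts[rec]) + L <= self.lengths[rec]
        keep = (mism <= m) & inside
        return t[keep], mism[keep].astype(np.int64)

    def search(self, query: str, max_mismatch: int) -> list[tuple[str, int, str, int]]:
        """All (record_id, position, strand, mismatches) window matches."""
        out = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            qcodes = encode(q)
            t = self._candidate_starts(qcodes, max_mismatch)
            t, mism = self._verify(qcodes, t, max_mismatch)
            rec = np.searchsorted(self.starts, t, side="right") - 1
            for ti, ri, mi in zip(t, rec, mism):
                out.append(
                    (self.record_ids[int(ri)], int(ti - self.starts[ri]), strand, int(mi))
                )
        out.sort(key=lambda h: (h[0], h[1], h[2]))
        return out


def find_protospacers(
    spacer: str,
    targets: Mapping[str, str] | TargetIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    spacer_ref: str = "",
    sample_id: str | None = None,
) -> list[ProtospacerHit]:
    """Every full-coverage window match of `spacer` on either strand of any
    target, at Hamming distance <= max_mismatch; sorted by (record, position)."""
    index = targets if isinstance(targets, TargetIndex) else TargetIndex(targets)
    hits = []
    for rid, pos, strand, mism in index.search(spacer, max_mismatch):
        hits.append(
            ProtospacerHit(
                spacer_ref=spacer_ref,
                target_id=rid,
                strand=strand,
                position=pos,
                mismatches=mism,
                length=len(spacer),
                sample_id=sample_id,
            )
        )
    return hits


def records_containing(
    query: str,
    targets: Mapping[str, str] | TargetIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> set[str]:
    index = targets if isinstance(targets, TargetIndex) else TargetIndex(targets)
    return {rid for rid, _, _, _ in index.search(query, max_mismatch)}


def apply_repeat_exclusion(
    hits: Sequence[ProtospacerHit],
    repeat: str,
    targets: Mapping[str, str] | TargetIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    contaminated: set[str] | None = None,
) -> list[ProtospacerHit]:
    """Flag (never delete) hits whose target record also matches the source
    array's repeat; pass `contaminated` to reuse a precomputed record set."""
    if contaminated is None:
        contaminated = records_containing(repeat, targets, max_mismatch)
    for h in hits:
        if h.target_id in contaminated:
            h.excluded = True
            h.exclusion_reason = "repeat_in_target"
    return list(hits)


def protospacer_fraction(
    spacer_refs: Sequence[str],
    hits: Sequence[ProtospacerHit],
) -> float:
    """Percent of the sample's spacers with at least one unexcluded hit."""
    if not spacer_refs:
        raise ValueError("protospacer fraction undefined for zero spacers")
    with_hit = {h.spacer_ref for h in hits if not h.excluded}
    return 100.0 * len(set(spacer_refs) & with_hit) / len(set(spacer_refs))


@dataclass
class PhageListComparison:
    list_case: set[str]
    list_control: set[str]
    intersection: set[str]
    family_counts: dict[str, dict[str, int]]  # group -> family -> hit count
    multi_protospacer_records: set[str] = field(default_factory=set)

    def family_abundance_pct(self, group: str) -> dict[str, float]:
        counts = self.family_counts.get(group, {})
        total = sum(counts.values())
        if total == 0:
            return {}
        return {fam: 100.0 * c / total for fam, c in counts.items()}


def compare_phage_lists(
    hits_by_group: Mapping[str, Sequence[ProtospacerHit]],
    target_meta: pd.DataFrame,
    multi_threshold: int = 4,
) -> PhageListComparison:
    """Per-group phage lists, their intersection, per-family hit counts and
    the records with more than `multi_threshold` protospacers in any group.

    Only unexcluded hits to records of kind 'phage' are considered; records
    with no family annotation are bucketed as 'unclassified'.
    """
    meta = target_meta.set_index("record_id")
    kind = meta["kind"].to_dict()
    family = meta["family"].fillna("").to_dict()

    lists: dict[str, set[str]] = {}
    fam_counts: dict[str, dict[str, int]] = {}
    per_record: dict[str, dict[str, int]] = {}
    for group, hits in hits_by_group.items():
        lists[group] = set()
        fam_counts[group] = {}
        per_record[group] = {}
        for h in hits:
            if h.excluded or kind.get(h.target_id) != "phage":
                continue
            lists[group].add(h.target_id)
            fam = family.get(h.target_id) or "unclassified"
            fam_counts[group][fam] = fam_counts[group].get(fam, 0) + 1
            per_record[group][h.target_id] = per_record[group].get(h.target_id, 0) + 1
    list_case = lists.get("case", set())
    list_control = lists.get("control", set())
    multi = {
        rid
        for group_counts in per_record.values()
        for rid, n in group_counts.items()
        if n > multi_threshold
    }
    return PhageListComparison(
        list_case=list_case,
        list_control=list_control,
        intersection=list_case & list_control,
        family_counts=fam_counts,
        multi_protospacer_records=multi,
    )


def hits_to_frame(hits: Sequence[ProtospacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spacer_ref": h.spacer_ref,
                "sample_id": h.sample_id,
                "target_id": h.target_id,
                "strand": h.strand,
                "position": h.position,
                "mismatches": h.mismatches,
                "length": h.length,
                "excluded": h.excluded,
                "exclusion_reason": h.exclusion_reason or "",
            }
            for h in hits
        ],
        columns=["spacer_ref", "sample_id", "target_id", "strand", "position",
                 "mismatches", "length", "excluded", "exclusion_reason"],
    )
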
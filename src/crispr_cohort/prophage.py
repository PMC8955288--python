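"""Prophage-context classification of protospacer locations.

Bacterial target records that provide protospacers to many distinct
samples are selected (strictly more than `min_samples`, default 10); each
unexcluded protospacer position on a selected record is then called
``prophage`` when it falls inside a supplied prophage region, or when a
gene overlapping it (or within the neighbour window) carries a
phage-keyword product annotation; otherwise ``non_prophage``.  Positions
on one record are additionally grouped into single-linkage location
clusters to expose the tight grouping typical of prophage-borne
protospacers.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .models import ContextCall, GffFeature, ProphageRegion, ProtospacerHit

PHAGE_KEYWORDS = [
    "phage", "prophage", "capsid", "tail", "terminase", "integrase",
    "portal", "holin", "lysin", "baseplate", "virion",
]

DEFAULT_MIN_SAMPLES = 10
DEFAULT_NEIGHBOUR_WINDOW = 1000
DEFAULT_MAX_GAP = 10_000


def select_multisample_records(
    hits: Sequence[ProtospacerHit],
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> list[str]:
    """Records whose unexcluded hits come from strictly more than
    `min_samples` distinct samples (group labels are ignored)."""
    samples_by_record: dict[str, set[str]] = {}
    for h in hits:
        if h.excluded or h.sample_id is None:
            continue
        samples_by_record.setdefault(h.target_id, set()).add(h.sample_id)
    return sorted(r for r, s in samples_by_record.items() if len(s) > min_samples)


def classify_context(
    hit: ProtospacerHit,
    regions: Sequence[ProphageRegion],
    genes: Sequence[GffFeature],
    window: int = DEFAULT_NEIGHBOUR_WINDOW,
    keywords: Sequence[str] = tuple(PHAGE_KEYWORDS),
) -> ContextCall:
    """Call one protospacer location prophage/non-prophage.

    `regions` and `genes` must belong to the hit's record; a record with no
    gene annotations is decided on regions alone and flagged low-evidence.
    """
    pos = hit.position
    evidence = set()
    if any(r.start <= pos < r.end for r in regions if r.record_id == hit.target_id):
        evidence.add("in_region")
    nearest: tuple[str, str, int] | None = None
    record_genes = [g for g in genes if g.seqid == hit.target_id]
    for g in record_genes:
        # distance 0 when the window [pos, pos+len) overlaps the gene
        dist = max(g.start - (pos + hit.length), pos - g.end, 0)
        if nearest is None or dist < nearest[2]:
            nearest = (
                g.attributes.get("ID", ""),
                g.attributes.get("product", ""),
                dist,
            )
        if dist <= window:
            product = g.attributes.get("product", "").lower()
            if any(k in product for k in keywords):
                evidence.add("phage_gene_annotation")
    return ContextCall(
        hit=hit,
        call="prophage" if evidence else "non_prophage",
        evidence=frozenset(evidence),
        nearest_gene=nearest,
        low_evidence=not record_genes,
    )


def group_positions(positions: Sequence[int], max_gap: int = DEFAULT_MAX_GAP) -> list[list[int]]:
    """Single-linkage clusters of positions on one record: consecutive
    sorted positions within `max_gap` join the same cluster."""
    if not positions:
        return []
    ordered = sorted(positions)
    clusters = [[ordered[0]]]
    for p in ordered[1:]:
        if p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def classify_record_hits(
    hits: Sequence[ProtospacerHit],
    regions: Sequence[ProphageRegion],
    genes: Sequence[GffFeature],
    window: int = DEFAULT_NEIGHBOUR_WINDOW,
) -> list[ContextCall]:
    by_record_regions: dict[str, list[ProphageRegion]] = {}
    for r in regions:
        by_record_regions.setdefault(r.record_id, []).append(r)
    by_record_genes: dict[str, list[GffFeature]] = {}
    for g in genes:
        by_record_genes.setdefault(g.seqid, []).append(g)
    return [
        classify_context(
            h,
            by_record_regions.get(h.target_id, []),
            by_record_genes.get(h.target_id, []),
            window=window,
        )
        for h in hits
        if not h.excluded
    ]


def prophage_summary(
    calls: Sequence[ContextCall],
    selected_records: Sequence[str],
    max_gap: int = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """One row per selected record: sample/hit counts, call tallies and the
    number of single-linkage location clusters."""
    rows = []
    by_record: dict[str, list[ContextCall]] = {}
    for c in calls:
        by_record.setdefault(c.hit.target_id, []).append(c)
    for rid in selected_records:
        record_calls = by_record.get(rid, [])
        positions = [c.hit.position for c in record_calls]
        rows.append(
            {
                "record_id": rid,
                "n_samples": len({c.hit.sample_id for c in record_calls if c.hit.sample_id}),
                "n_hits": len(record_calls),
                "n_prophage": sum(1 for c in record_calls if c.call == "prophage"),
                "n_non_prophage": sum(1 for c in record_calls if c.call == "non_prophage"),
                "n_location_clusters": len(group_positions(positions, max_gap)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["record_id", "n_samples", "n_hits", "n_prophage",
                 "n_non_prophage", "n_location_clusters"],
    )


def calls_to_frame(calls: Sequence[ContextCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": c.hit.target_id,
                "position": c.hit.position,
                "sample_id": c.hit.sample_id or "",
                "spacer_ref": c.hit.spacer_ref,
                "call": c.call,
                "evidence": ",".join(sorted(c.evidence)),
                "nearest_gene": c.nearest_gene[0] if c.nearest_gene else "",
                "nearest_gene_product": c.nearest_gene[1] if c.nearest_gene else "",
                "nearest_gene_distance": c.nearest_gene[2] if c.nearest_gene else -1,
                "low_evidence": c.low_evidence,
            }
            for c in calls
        ],
        columns=["target_id", "position", "sample_id", "spacer_ref", "call",
                 "evidence", "nearest_gene", "nearest_gene_product",
                 "nearest_gene_distance", "low_evidence"],
    )
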
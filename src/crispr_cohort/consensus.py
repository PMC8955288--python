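"""Consensus retention of candidate arrays.

A candidate equivalence class (cross-detector candidates matched by
reciprocal interval overlap) is kept when it was predicted by every
configured detector simultaneously, or when it carries biological support:
co-localisation with an annotated cas locus, or membership of a direct-
repeat similarity cluster shared with at least one other array.  The
repeat clustering is the greedy seed-and-absorb scheme used by DNACLUST,
with similarity taken as 1 - editDistance/max(length) in the best of the
forward and reverse-complement orientations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import edlib

from ._seq import is_dna, revcomp
from .models import (
    CandidateArray,
    CasLocus,
    GffFeature,
    RepeatCluster,
    ValidatedArray,
)

CAS_LEXICON = (
    [f"cas{i}" for i in range(1, 15)]
    + ["csn", "cse", "csy", "csm", "cmr", "csf", "cas9", "cas12", "cas13",
       "crispr-associated"]
)


@dataclass
class ValidationParams:
    cas_proximity_window: int = 1000
    min_reciprocal_overlap: float = 0.5
    cluster_similarity_threshold: float = 0.8
    min_cluster_arrays: int = 2
    cluster_scope: str = "cohort"  # or "sample": restrict support to same-sample clusters
    min_flank_complete: int = 200


class ConfigurationError(ValueError):
    pass


def repeat_similarity(a: str, b: str) -> tuple[float, str]:
    """Similarity in [0, 1] maximized over the orientation of ``b``.

    similarity = 1 - editDistance(a, b*) / max(len(a), len(b*)) with
    b* in {b, revcomp(b)}.  N is allowed and scores as a mismatch against
    any other base.  Returns (similarity, orientation) with orientation in
    {"forward", "revcomp"}.
    """
    if not a or not b:
        raise ValueError("repeat similarity needs non-empty sequences")
    for s in (a, b):
        if not is_dna(s):
            raise ValueError("repeat sequences must be DNA over ACGT(N)")
    a = a.upper()
    best = (-1.0, "forward")
    for orient, bb in (("forward", b.upper()), ("revcomp", revcomp(b.upper()))):
        d = edlib.align(a, bb, task="distance", mode="NW")["editDistance"]
        sim = 1.0 - d / max(len(a), len(bb))
        if sim > best[0]:
            best = (sim, orient)
    return best


def cluster_repeats(
    repeats: list[tuple[str, str, str]],
    threshold: float = 0.8,
) -> list[RepeatCluster]:
    """Greedy clustering of (repeat, sample_id, array_ref) tuples.

    Repeats are sorted by decreasing length (ties lexicographic); the first
    unclustered repeat seeds a cluster and absorbs every unclustered repeat
    whose best-orientation similarity to the seed is >= threshold.  The
    partition is exhaustive, disjoint and deterministic.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    order = sorted(range(len(repeats)), key=lambda i: (-len(repeats[i][0]), repeats[i][0], repeats[i][1], repeats[i][2]))
    unclustered = list(order)
    clusters: list[RepeatCluster] = []
    while unclustered:
        seed_i = unclustered.pop(0)
        seed = repeats[seed_i][0]
        members = [repeats[seed_i]]
        rest = []
        for i in unclustered:
            sim, _ = repeat_similarity(seed, repeats[i][0])
            if sim >= threshold:
                members.append(repeats[i])
            else:
                rest.append(i)
        unclustered = rest
        clusters.append(
            RepeatCluster(
                cluster_id=f"DRC{len(clusters) + 1:04d}",
                seed_repeat=seed,
                members=members,
                similarity_threshold=threshold,
            )
        )
    return clusters


def match_candidates(a: CandidateArray, b: CandidateArray,
                     min_reciprocal_overlap: float = 0.5) -> bool:
    """True iff the two intervals overlap by at least the stated fraction
    of BOTH lengths (same contig required); symmetric."""
    if a.contig_id != b.contig_id:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return (ov >= min_reciprocal_overlap * (a.end - a.start)
            and ov >= min_reciprocal_overlap * (b.end - b.start))


def cas_loci_from_gff(features: list[GffFeature]) -> list[CasLocus]:
    """Extract cas loci from gene/CDS features whose Name/gene/product
    attributes match the cas lexicon (case-insensitive substring)."""
    out = []
    for f in features:
        if f.type not in ("gene", "CDS"):
            continue
        text = " ".join(
            f.attributes.get(k, "") for k in ("Name", "gene", "product")
        ).lower()
        names = [w for w in CAS_LEXICON if w in text]
        if names:
            out.append(CasLocus(f.seqid, f.start, f.end, names))
    return out


def _near_cas(start: int, end: int, loci: list[CasLocus], contig_id: str,
              window: int) -> bool:
    for locus in loci:
        if locus.contig_id != contig_id:
            continue
        gap = max(locus.start - end, start - locus.end, 0)
        if gap <= window:
            return True
    return False


def _equivalence_classes(cands: list[CandidateArray],
                         min_overlap: float) -> list[list[CandidateArray]]:
    """Group cross-detector candidates by transitive closure of
    match_candidates."""
    by_contig: dict[str, list[CandidateArray]] = {}
    for c in cands:
        by_contig.setdefault(c.contig_id, []).append(c)
    classes: list[list[CandidateArray]] = []
    for contig_cands in by_contig.values():
        contig_cands.sort(key=lambda c: (c.start, c.end, c.detector_id))
        parent = list(range(len(contig_cands)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(contig_cands)), 2):
            if match_candidates(contig_cands[i], contig_cands[j], min_overlap):
                parent[find(i)] = find(j)
        groups: dict[int, list[CandidateArray]] = {}
        for i, c in enumerate(contig_cands):
            groups.setdefault(find(i), []).append(c)
        classes.extend(groups.values())
    classes.sort(key=lambda g: (g[0].contig_id, min(c.start for c in g)))
    return classes


def validate(
    candidates_by_detector: dict[str, list[CandidateArray]],
    cas_loci: list[CasLocus],
    sample_id: str,
    contig_lengths: dict[str, int],
    params: ValidationParams | None = None,
    cluster_membership: dict[str, RepeatCluster] | None = None,
) -> list[ValidatedArray]:
    """Apply the retention rule to one sample's candidate sets.

    `cluster_membership` maps provisional class ids (see
    :func:`class_id_for`) to the cohort-wide repeat cluster holding the
    class representative's consensus; pass None to skip cluster support
    (e.g. on a first pass used to harvest repeats for clustering).
    """
    params = params or ValidationParams()
    if not candidates_by_detector:
        raise ConfigurationError("at least one detector's candidate set is required")
    detector_ids = set(candidates_by_detector)
    all_cands = [c for cands in candidates_by_detector.values() for c in cands]
    classes = _equivalence_classes(all_cands, params.min_reciprocal_overlap)

    out: list[ValidatedArray] = []
    for cls in classes:
        rep = max(cls, key=lambda c: (c.n_copies, -c.start))
        cid = class_id_for(sample_id, rep)
        supporting = frozenset(c.detector_id for c in cls)
        support = set()
        if detector_ids <= supporting:
            support.add("all_detectors")
        if _near_cas(rep.start, rep.end, cas_loci, rep.contig_id,
                     params.cas_proximity_window):
            support.add("cas_adjacent")
        cluster = (cluster_membership or {}).get(cid)
        if cluster is not None:
            arrays = cluster.member_arrays()
            if params.cluster_scope == "sample":
                arrays = {
                    a for (r, s, a) in cluster.members if s == sample_id
                }
            if len(arrays) >= max(params.min_cluster_arrays, 2):
                support.add("repeat_cluster")
        if not support:
            continue
        clen = contig_lengths[rep.contig_id]
        left, right = rep.start, clen - rep.end
        out.append(
            ValidatedArray(
                contig_id=rep.contig_id,
                start=rep.start,
                end=rep.end,
                repeat_consensus=rep.repeat_consensus,
                repeat_copies=rep.repeat_copies,
                spacers=rep.spacers,
                detector_id=rep.detector_id,
                sample_id=sample_id,
                supporting_detectors=supporting,
                support=frozenset(support),
                left_flank=left,
                right_flank=right,
                complete=(left >= params.min_flank_complete
                          and right >= params.min_flank_complete),
                cluster_id=cluster.cluster_id if cluster is not None else None,
                array_id=cid,
            )
        )
    out.sort(key=lambda v: (v.contig_id, v.start))
    return out


def class_id_for(sample_id: str, representative: CandidateArray) -> str:
    """Stable id for a candidate equivalence class (used as the array ref
    in repeat clusters)."""
    return f"{sample_id}:{representative.contig_id}:{representative.start}"


def candidate_classes(
    candidates_by_detector: dict[str, list[CandidateArray]],
    sample_id: str,
    min_reciprocal_overlap: float = 0.5,
) -> list[tuple[str, CandidateArray]]:
    """(class_id, representative) for each cross-detector equivalence class;
    the representative's consensus is what enters repeat clustering."""
    all_cands = [c for cands in candidates_by_detector.values() for c in cands]
    classes = _equivalence_classes(all_cands, min_reciprocal_overlap)
    out = []
    for cls in classes:
        rep = max(cls, key=lambda c: (c.n_copies, -c.start))
        out.append((class_id_for(sample_id, rep), rep))
    return out
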
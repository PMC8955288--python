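"""Built-in CRISPR array detectors plus an adapter for external tool output.

Two independent strategies are provided so that downstream consensus
validation has genuinely distinct evidence sources:

``detect_kmer_periodic``
    CRT-style: short exact k-mers (default k=8) recurring at quasi-regular
    intervals seed a candidate; the seed match is extended to a full repeat
    copy, further copies are chained through spacer-length windows, and
    repeat boundaries are refined by column-wise agreement across copies.

``detect_maximal_repeat``
    PILER-style: exact repeated substrings of at least the minimum repeat
    length are enumerated genome-wide and their occurrence pairs chained
    into arrays; the same growth/refinement core is reused, but discovery
    does not rely on short-seed periodicity and tolerates a skipped
    (mutated) copy between anchor occurrences.

Both emit non-overlapping, start-sorted :class:`CandidateArray` records
whose text reconstructs exactly from the contig.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import encode, hamming, kmer_hashes
from .io import ParseError
from .models import CandidateArray

log = logging.getLogger("crispr_cohort")


@dataclass
class DetectorParams:
    """Geometry and tolerance settings shared by the built-in detectors."""

    repeat_len_range: tuple[int, int] = (19, 48)
    spacer_len_range: tuple[int, int] = (17, 72)
    min_repeat_copies: int = 3
    max_repeat_copy_edits: int = 3
    kmer_seed_len: int = 8

    def __post_init__(self) -> None:
        if self.min_repeat_copies < 2:
            raise ValueError("min_repeat_copies must be >= 2")
        for r in (self.repeat_len_range, self.spacer_len_range):
            if not (len(r) == 2 and 0 < r[0] <= r[1]):
                raise ValueError("length ranges must be non-empty (min, max)")


def _seed_pairs(codes: np.ndarray, k: int, dmin: int, dmax: int):
    """(p, q) position pairs sharing an exact k-mer with q - p in [dmin, dmax]."""
    h = kmer_hashes(codes, k)
    idx = np.flatnonzero(h >= 0)
    if idx.size < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    hv = h[idx]
    order = np.argsort(hv, kind="stable")  # ties keep ascending positions
    hs = hv[order]
    ps = idx[order]
    same = hs[1:] == hs[:-1]
    gaps = ps[1:] - ps[:-1]
    mask = same & (gaps >= dmin) & (gaps <= dmax)
    return ps[:-1][mask], ps[1:][mask]


def _extend_exact(codes: np.ndarray, p: int, q: int, k: int) -> tuple[int, int]:
    """Maximal exact match block around seed p/q; returns (block_start, block_len)."""
    n = codes.size
    left = 0
    while p - left - 1 >= 0 and codes[p - left - 1] == codes[q - left - 1]:
        left += 1
    right = 0
    while q + k + right < n and codes[p + k + right] == codes[q + k + right]:
        right += 1
        if p + k + right > q:  # template may not run past its partner
            break
    return p - left, left + k + right


def _window_mismatches(codes: np.ndarray, t: int, template: np.ndarray) -> int:
    return int(np.count_nonzero(codes[t : t + template.size] != template))


def _chain(codes: np.ndarray, anchor: int, template: np.ndarray, params: DetectorParams):
    """Chain repeat copies left and right of the anchor occurrence.

    Steps through spacer-length windows, at each step taking the window
    offset with the fewest mismatches to the template (ties -> leftmost),
    with a tolerance loose enough to survive boundary slop; boundaries are
    fixed afterwards by `_refine`.
    """
    n = codes.size
    L = template.size
    rmin = params.repeat_len_range[0]
    smin, smax = params.spacer_len_range
    tol = params.max_repeat_copy_edits + 2
    starts = [anchor]
    # rightwards
    cur = anchor
    while True:
        lo = cur + rmin + smin
        hi = min(cur + L + smax, n - L)
        best_t, best_m = None, tol + 1
        for t in range(lo, hi + 1):
            m = _window_mismatches(codes, t, template)
            if m < best_m:
                best_t, best_m = t, m
        if best_t is None or best_m > tol:
            break
        starts.append(best_t)
        cur = best_t
    # leftwards
    cur = anchor
    while True:
        lo = max(cur - L - smax, 0)
        hi = cur - rmin - smin
        if hi < 0:
            break
        best_t, best_m = None, tol + 1
        for t in range(lo, hi + 1):
            m = _window_mismatches(codes, t, template)
            if m < best_m:
                best_t, best_m = t, m
        if best_t is None or best_m > tol:
            break
        starts.insert(0, best_t)
        cur = best_t
    return starts


def _refine(codes: np.ndarray, starts: list[int], off: int, seed_len: int,
            params: DetectorParams) -> tuple[list[int], int]:
    """Fix repeat boundaries by extending the seed columns while every
    chained copy agrees, bounded by the repeat-length maximum and by the
    requirement that inter-copy gaps keep room for a minimal spacer."""
    n = codes.size
    rmax = params.repeat_len_range[1]
    smin = params.spacer_len_range[0]
    arr = np.asarray(starts)
    min_gap = int(np.diff(arr).min()) if arr.size > 1 else rmax + smin
    max_len = min(rmax, min_gap - smin)
    lo, hi = off, off + seed_len  # column window relative to copy starts
    if hi - lo > max_len:
        hi = lo + max_len

    def _agree(col: int) -> bool:
        pos = arr + col
        if pos[0] < 0 or pos[-1] >= n:
            return False
        vals = codes[pos]
        return bool((vals == vals[0]).all())

    # the seed block was built from one copy pair and may overrun the true
    # boundary where just those two copies agree by chance: shrink to the
    # columns where every chained copy agrees, then extend outwards
    while lo < hi and not _agree(lo):
        lo += 1
    while hi > lo and not _agree(hi - 1):
        hi -= 1
    while hi - lo < max_len and _agree(lo - 1):
        lo -= 1
    while hi - lo < max_len and _agree(hi):
        hi += 1
    return [int(s) + lo for s in starts], hi - lo


def _consensus(copies: list[str]) -> str:
    """Column-wise majority consensus; ties broken alphabetically."""
    out = []
    for col in zip(*copies):
        counts = Counter(col)
        top = max(counts.values())
        out.append(min(b for b, c in counts.items() if c == top))
    return "".join(out)


def _build_candidate(seq: str, codes: np.ndarray, starts: list[int], L: int,
                     contig_id: str, detector_id: str,
                     params: DetectorParams) -> CandidateArray | None:
    smin, smax = params.spacer_len_range
    # trim end copies that disagree too much with the consensus
    while len(starts) >= 2:
        copies = [seq[s : s + L] for s in starts]
        cons = _consensus(copies)
        bad_first = hamming(copies[0], cons) > params.max_repeat_copy_edits
        bad_last = hamming(copies[-1], cons) > params.max_repeat_copy_edits
        if not bad_first and not bad_last:
            break
        if bad_last:
            starts = starts[:-1]
        elif bad_first:
            starts = starts[1:]
    if len(starts) < params.min_repeat_copies:
        return None
    copies = [seq[s : s + L] for s in starts]
    spacers = [seq[starts[i] + L : starts[i + 1]] for i in range(len(starts) - 1)]
    if any(not (smin <= len(sp) <= smax) for sp in spacers):
        return None
    if len(set(spacers)) != len(spacers):
        return None  # tandem/low-complexity loci masquerading as arrays
    cons = _consensus(copies)
    return CandidateArray(
        contig_id=contig_id,
        start=starts[0],
        end=starts[-1] + L,
        repeat_consensus=cons,
        repeat_copies=copies,
        spacers=spacers,
        detector_id=detector_id,
    )


def _grow_from_pairs(seq: str, codes: np.ndarray, pairs, seed_len: int,
                     contig_id: str, detector_id: str,
                     params: DetectorParams) -> list[CandidateArray]:
    rmin, rmax = params.repeat_len_range
    smin = params.spacer_len_range[0]
    found: list[CandidateArray] = []
    covered: list[tuple[int, int]] = []
    p_arr, q_arr = pairs
    order = np.argsort(p_arr, kind="stable")
    for i in order:
        p, q = int(p_arr[i]), int(q_arr[i])
        if any(s <= p < e for s, e in covered):
            continue
        bs, bl = _extend_exact(codes, p, q, seed_len)
        if bl < rmin:
            continue
        d = q - p
        t_len = min(bl, rmax, d - smin)
        if t_len < rmin:
            continue
        template = codes[bs : bs + t_len]
        starts = _chain(codes, bs, template, params)
        if len(starts) < params.min_repeat_copies:
            continue
        starts, L = _refine(codes, starts, 0, t_len, params)
        if L < rmin:
            continue
        cand = _build_candidate(seq, codes, starts, L, contig_id, detector_id, params)
        if cand is None:
            continue
        if any(not (cand.end <= s or cand.start >= e) for s, e in covered):
            continue
        found.append(cand)
        covered.append((cand.start, cand.end))
    found.sort(key=lambda c: c.start)
    return found


def detect_kmer_periodic(contig_id: str, seq: str,
                         params: DetectorParams | None = None) -> list[CandidateArray]:
    """Detect arrays via short seeds recurring at repeat+spacer periods."""
    params = params or DetectorParams()
    if len(seq) < 200:
        return []
    codes = encode(seq)
    k = params.kmer_seed_len
    dmin = params.repeat_len_range[0] + params.spacer_len_range[0]
    dmax = params.repeat_len_range[1] + params.spacer_len_range[1]
    pairs = _seed_pairs(codes, k, dmin, dmax)
    return _grow_from_pairs(seq, codes, pairs, k, contig_id, "kmer", params)


def detect_maximal_repeat(contig_id: str, seq: str,
                          params: DetectorParams | None = None) -> list[CandidateArray]:
    """Detect arrays by chaining occurrences of exact repeats of at least
    the minimum repeat length (window wide enough to skip a mutated copy)."""
    params = params or DetectorParams()
    if len(seq) < 200:
        return []
    codes = encode(seq)
    k = params.repeat_len_range[0]
    dmin = params.repeat_len_range[0] + params.spacer_len_range[0]
    dmax = 2 * (params.repeat_len_range[1] + params.spacer_len_range[1])
    pairs = _seed_pairs(codes, k, dmin, dmax)
    return _grow_from_pairs(seq, codes, pairs, k, contig_id, "maxrep", params)


BUILTIN_DETECTORS = {
    "kmer": detect_kmer_periodic,
    "maxrep": detect_maximal_repeat,
}


def detect_contigs(contigs: dict[str, str], detector_id: str,
                   params: DetectorParams | None = None) -> list[CandidateArray]:
    """Run one built-in detector over a contig set."""
    fn = BUILTIN_DETECTORS[detector_id]
    out: list[CandidateArray] = []
    for cid, seq in contigs.items():
        out.extend(fn(cid, seq, params))
    return out


ADAPTER_COLUMNS = ["contig_id", "start", "end", "repeat_consensus", "spacers", "detector_id"]


def load_external_candidates(path: str | Path, contigs: dict[str, str],
                             detector_id: str | None = None,
                             max_copy_edits: int = 3,
                             min_copies: int = 2) -> list[CandidateArray]:
    """Load candidates from the adapter TSV dialect and re-validate them
    against the supplied contigs; rows failing the array invariants are
    rejected with a logged reason."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "spacers": str})
    except pd.errors.EmptyDataError:
        return []
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"malformed adapter file {path}: {exc}") from exc
    missing = set(ADAPTER_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing adapter columns {sorted(missing)}")
    out: list[CandidateArray] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        reason = None
        try:
            start, end = int(row.start), int(row.end)
            spacers = [] if pd.isna(row.spacers) or row.spacers == "" else str(row.spacers).split(",")
            cons = str(row.repeat_consensus)
            det = detector_id or str(row.detector_id)
            contig = contigs.get(str(row.contig_id))
            if contig is None:
                reason = f"unknown contig {row.contig_id!r}"
            else:
                # carve repeat copies between the stated spacers
                L = len(cons)
                copies, pos, ok = [], start, True
                for sp in spacers + [None]:
                    copies.append(contig[pos : pos + L])
                    pos += L
                    if sp is not None:
                        if contig[pos : pos + len(sp)] != sp:
                            ok = False
                            break
                        pos += len(sp)
                if not ok or pos != end:
                    reason = "reconstructed array text does not match contig"
                else:
                    cand = CandidateArray(str(row.contig_id), start, end, cons,
                                          copies, spacers, det)
                    if cand.n_copies < min_copies:
                        reason = "fewer than the minimum repeat copies"
                    else:
                        cand.check(contig, max_copy_edits=max_copy_edits)
                        out.append(cand)
        except (ValueError, TypeError) as exc:
            reason = str(exc)
        if reason:
            log.warning("%s line %d rejected: %s", path, lineno, reason)
    return out


def candidates_to_frame(cands: list[CandidateArray]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "start": c.start,
                "end": c.end,
                "repeat_consensus": c.repeat_consensus,
                "spacers": ",".join(c.spacers),
                "detector_id": c.detector_id,
            }
            for c in cands
        ],
        columns=ADAPTER_COLUMNS,
    )
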
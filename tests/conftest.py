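"""Shared fixtures: a small planted-truth cohort and brute-force oracles.

The oracles re-derive expected results by exhaustive scanning, independent
of the package's seeded/indexed implementations, so detector and search
outputs can be checked against ground truth computed a second way.
"""

from __future__ import annotations

import numpy as np
import pytest

from crispr_cohort import CohortConfig, generate_cohort
from crispr_cohort._seq import encode, revcomp


@pytest.fixture(scope="session")
def small_bundle():
    """A modest clean cohort (mutation rate 0) with protospacers, decoys,
    prophage islands and both series, shared by read-only tests."""
    cfg = CohortConfig(
        n_case=4,
        n_control=4,
        series_labels=("I", "II"),
        assembly_size_per_sample=2_000_000,
        assembly_size_cv=0.2,
        contig_length_distribution=(1_000, 30_000),
        array_density_case=4_000.0,
        array_density_control=4_500.0,
        repeat_mutation_rate=0.0,
        cas_adjacent_fraction=0.3,
        truncated_fraction=0.4,
        n_phage_records=6,
        n_bacterial_records=3,
        phage_record_length=20_000,
        bacterial_record_length=60_000,
        prophage_island_length=20_000,
        protospacer_planting_rate=0.3,
        decoy_array_in_target_rate=0.9,
        seed=424,
    )
    return generate_cohort(cfg)


def bf_hamming_hits(query: str, records: dict[str, str], max_mismatch: int):
    """Exhaustive all-window Hamming scan on both strands.

    Returns the full hit set as {(record_id, position, strand, mismatches)}.
    """
    out = set()
    for strand, q in (("+", query), ("-", revcomp(query))):
        qc = encode(q)
        L = qc.size
        for rid, seq in records.items():
            codes = encode(seq)
            if codes.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, L)
            mism = np.count_nonzero(windows != qc[None, :], axis=1)
            for pos in np.flatnonzero(mism <= max_mismatch):
                out.add((rid, int(pos), strand, int(mism[pos])))
    return out


def bf_find_regular_arrays(seq: str, repeat_len_range=(19, 48),
                           spacer_len_range=(17, 72), min_copies=3):
    """Exhaustive scan for arrays of >= min_copies EXACTLY equal repeat
    copies at one fixed period (constant spacer length), with pairwise
    distinct spacers.  Returns maximal (start, end, n_copies) intervals.

    This is the independent oracle for the detectors on clean input with
    constant-length spacers; it shares no code with the detectors.
    """
    n = len(seq)
    found = []
    rmin, rmax = repeat_len_range
    smin, smax = spacer_len_range
    for L in range(rmin, rmax + 1):
        for d in range(L + smin, L + smax + 1):
            s = 0
            while s + d + L <= n:
                if seq[s : s + L] != seq[s + d : s + d + L]:
                    s += 1
                    continue
                copies = 2
                while s + copies * d + L <= n and seq[s : s + L] == seq[s + copies * d : s + copies * d + L]:
                    copies += 1
                recorded = False
                if copies >= min_copies:
                    spacers = [seq[s + i * d + L : s + (i + 1) * d] for i in range(copies - 1)]
                    if len(set(spacers)) == len(spacers):
                        found.append((s, s + (copies - 1) * d + L, copies))
                        recorded = True
                # only skip past runs actually recorded; a chance sub-minimal
                # match must not let the scan jump over a real run start
                s += copies * d if recorded else 1
    # keep only maximal intervals (drop those contained in a longer one)
    maximal = []
    for iv in found:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv for o in found):
            maximal.append(iv)
    return sorted(set(maximal))


def truth_arrays(bundle):
    return [a for a in bundle.arrays]


def groups_of(bundle) -> dict[str, str]:
    return dict(zip(bundle.metadata["sample_id"], bundle.metadata["group"]))
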
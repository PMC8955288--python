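"""Low-level sequence utilities shared by the detectors and search engines.

Sequences are plain upper-case strings over ACGTN.  Numeric work (k-mer
hashing, windowed Hamming comparisons) runs on uint8 code arrays where
A=0, C=1, G=2, T=3 and N=4; any window containing an N code is excluded
from exact k-mer hashing.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte value -> code; 255 marks characters that are not ACGTN
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[ord(chr(_b).lower())] = _i
_CODE_TABLE[ord("N")] = 4
_CODE_TABLE[ord("n")] = 4

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, allow_n: bool = True) -> bool:
    allowed = set("ACGTacgt" + ("Nn" if allow_n else ""))
    return bool(seq) and set(seq) <= allowed


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A0 C1 G2 T3 N4)."""
    codes = _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() == 255:
        bad = chr(int(np.frombuffer(seq.encode("ascii"), np.uint8)[codes == 255][0]))
        raise ValueError(f"non-DNA character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return bytes(np.frombuffer(b"ACGTN", np.uint8)[codes]).decode("ascii")


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Exact 2-bit rolling hashes of every k-window; -1 where the window
    contains an N/invalid code.  Requires k <= 31."""
    if k > 31:
        raise ValueError("k-mer hash supports k <= 31 (2 bits per base in int64)")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        h = (h << 2) | (col & 3)
        valid &= col < 4
    h[~valid] = -1
    return h


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. ACGT string."""
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return bytes(np.frombuffer(b"ACGT", np.uint8)[codes]).decode("ascii")


def mutate_substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    """Independent per-base substitution at `rate`; substitutions always
    change the base (drawn from the three alternatives)."""
    if rate <= 0:
        return seq
    codes = encode(seq).copy()
    hit = rng.random(codes.size) < rate
    if not hit.any():
        return seq
    shifts = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    codes[hit] = (codes[hit] + shifts) % 4
    return decode(codes)


def mutate_exactly(
    rng: np.random.Generator, seq: str, n_mismatches: int
) -> str:
    """Substitute exactly `n_mismatches` distinct positions, each to a
    different base, so the Hamming distance to `seq` is exact."""
    if n_mismatches > len(seq):
        raise ValueError("more mismatches requested than sequence length")
    codes = encode(seq).copy()
    pos = rng.choice(len(seq), size=n_mismatches, replace=False)
    shifts = rng.integers(1, 4, size=n_mismatches, dtype=np.uint8)
    codes[pos] = (codes[pos] + shifts) % 4
    return decode(codes)
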
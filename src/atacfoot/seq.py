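"""Base-level sequence utilities: encoding, reverse complement, hexamer indexing.

Sequences are handled internally as uint8 code arrays (A=0, C=1, G=2, T=3,
anything else=4).  Hexamers are indexed 0..4095 in base-4 big-endian order,
so ``AAAAAA`` = 0 and ``TTTTTT`` = 4095.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4
HEXAMER_K = 6
N_HEXAMERS = 4**HEXAMER_K

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 renders as ``N``."""
    return _DECODE[np.minimum(codes, N_CODE)].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array; N stays N."""
    out = codes[::-1].copy()
    acgt = out < N_CODE
    out[acgt] = 3 - out[acgt]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_index_table(codes: np.ndarray, k: int = HEXAMER_K) -> tuple[np.ndarray, np.ndarray]:
    """Index of the k-mer starting at each position, plus a validity mask.

    Returns ``(idx, valid)`` of length ``len(codes) - k + 1``; windows
    containing a non-ACGT base are invalid (their index is meaningless).
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        window = codes[i : i + n]
        bad = window >= N_CODE
        valid &= ~bad
        idx = idx * 4 + np.where(bad, 0, window)
    return idx, valid


def revcomp_kmer_table(k: int = HEXAMER_K) -> np.ndarray:
    """Lookup table mapping each k-mer index to its reverse complement's index."""
    n = 4**k
    idx = np.arange(n)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        digit = (idx >> (2 * (k - 1 - i))) & 3
        out += (3 - digit) << (2 * i)
    return out


def kmer_to_index(kmer: str) -> int:
    codes = encode(kmer)
    if (codes >= N_CODE).any():
        raise ValueError(f"k-mer contains non-ACGT base: {kmer!r}")
    return int(sum(int(c) * 4 ** (len(codes) - 1 - i) for i, c in enumerate(codes)))


def index_to_kmer(index: int, k: int = HEXAMER_K) -> str:
    out = []
    for i in range(k):
        out.append(BASES[(index >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def gc_fraction_of_codes(codes: np.ndarray) -> float:
    """(G+C) / (A+C+G+T); NaN when the span is all non-ACGT."""
    acgt = codes < N_CODE
    denom = int(acgt.sum())
    if denom == 0:
        return float("nan")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / denom
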
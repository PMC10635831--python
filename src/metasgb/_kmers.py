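"""Low-level 2-bit k-mer encoding, rolling k-mer codes and MinHash hashing.

All heavy per-base work is vectorised with numpy; k is limited to 31 so a
k-mer fits a 64-bit code (2 bits per base).
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = np.full(256, ord("N"), dtype=np.uint8)
for _a, _b in zip(b"ACGTacgtNn", b"TGCATGCANN"):
    _COMP[_a] = _b


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, other=255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[min(int(c), 4)] for c in arr)


def revcomp(seq: str) -> str:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _COMP[raw][::-1].tobytes().decode("ascii")


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit codes of all k-mers of an encoded sequence.

    Returns (codes, valid) where valid masks windows free of ambiguous bases.
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    a = arr.astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | (a[j : j + n] & np.uint64(3))
    bad = (arr > 3).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[k:] - cum[:-k]) == 0
    return codes, valid


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement 2-bit k-mer codes (vectorised)."""
    out = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | ((c & np.uint64(3)) ^ np.uint64(3))
        c >>= np.uint64(2)
    return out


def canonical_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-independent) codes of valid k-mers of a sequence."""
    codes, valid = kmer_codes(arr, k)
    codes = codes[valid]
    rc = revcomp_codes(codes, k)
    return np.minimum(codes, rc)


def mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finaliser; a well-mixed deterministic 64-bit hash."""
    x = x.astype(np.uint64, copy=True)
    x += np.uint64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    x = x ^ (x >> np.uint64(31))
    return x


def bottom_hashes(arr: np.ndarray, k: int, s: int) -> np.ndarray:
    """The s smallest distinct canonical k-mer hashes of an encoded sequence."""
    hashes = np.unique(mix64(canonical_codes(arr, k)))
    return hashes[:s]
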
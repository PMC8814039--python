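"""Vectorised canonical k-mer extraction.

Two encodings are used:

* exact 2-bit packing for k <= 31 (anchor and validation k-mers), where the
  canonical form is the numeric minimum of the forward and reverse-complement
  codes — identical to taking the lexicographic minimum of the two strings
  under the A<C<G<T byte order;
* a 64-bit polynomial rolling hash for larger k (the 100-mer depth signal),
  where min(hash(fwd), hash(rc)) serves as a strand-independent identifier.
  Hash collisions between unrelated k-mers are ~n^2 / 2^64 and negligible at
  the genome sizes this package handles.

Positions whose window contains a non-ACGT base are flagged invalid and take
no part in matching.
"""

from __future__ import annotations

import numpy as np

# byte -> 2-bit code; anything not ACGT (upper or lower) maps to -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_HASH_BASE = np.uint64(0x100000001B3)  # FNV-64 prime; odd, so multiplication is a bijection mod 2^64


def encode(seq: str | bytes) -> np.ndarray:
    """Map a DNA string to int8 codes (A=0, C=1, G=2, T=3, other=-1)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def _window_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over start positions: True where the k-window is all ACGT."""
    bad = (codes < 0).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    return (cs[k:] - cs[:-k]) == 0


def _roll(codes: np.ndarray, k: int, base: np.uint64) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement window values under Horner evaluation.

    fwd[i]  = sum_j codes[i+j]     * base^(k-1-j)   (mod 2^64)
    rc[i]   = sum_j (3-codes[i+j]) * base^j         (mod 2^64)
    """
    n = codes.size - k + 1
    c = np.where(codes < 0, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    pow_int = 1
    with np.errstate(over="ignore"):  # uint64 wraparound is the point
        for j in range(k):
            w = c[j : j + n]
            fwd = fwd * base + w
            rc = rc + (three - w) * np.uint64(pow_int)
            pow_int = (pow_int * int(base)) & 0xFFFFFFFFFFFFFFFF
    return fwd, rc


def canonical_kmers(
    seq: str | bytes, k: int, *, exact: bool | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical k-mer codes for every start position of ``seq``.

    Returns ``(codes, fwd_is_canonical, valid)`` — each of length
    ``len(seq) - k + 1`` (empty if the sequence is shorter than k).
    ``exact`` forces 2-bit packing (k <= 31) or hashing; default is by k.
    """
    codes = encode(seq)
    if codes.size < k:
        z = np.zeros(0, dtype=np.uint64)
        return z, np.zeros(0, dtype=bool), np.zeros(0, dtype=bool)
    if exact is None:
        exact = k <= 31
    if exact and k > 31:
        raise ValueError("exact 2-bit packing requires k <= 31")
    base = np.uint64(4) if exact else _HASH_BASE
    fwd, rc = _roll(codes, k, base)
    canon = np.minimum(fwd, rc)
    return canon, fwd <= rc, _window_valid(codes, k)


def valid_canonical(seq: str | bytes, k: int, *, exact: bool | None = None) -> np.ndarray:
    """Canonical codes at valid start positions only (order preserved)."""
    canon, _, valid = canonical_kmers(seq, k, exact=exact)
    return canon[valid]


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
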
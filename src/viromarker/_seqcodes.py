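"""Numeric sequence kernel: 2-bit-style encoding and k-mer hashing.

Residues are mapped A,C,G,T -> 0..3 and N -> 4 (``CODE_N``). Every window
that contains an N is treated as invalid by the k-mer and matching stages.
Hashes are base-4 ranks in lexicographic order (A<C<G<T), so a k-mer hash
doubles as its index into a dense 4**k count vector. k is capped at 31 so
ranks fit in uint64.
"""

from __future__ import annotations

import numpy as np

CODE_N = 4
MAX_K = 31

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_ENCODE[ord("N")] = CODE_N
_ENCODE[ord("n")] = CODE_N

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMPLEMENT = np.array([3, 2, 1, 0, CODE_N], dtype=np.uint8)


def encode(residues: str) -> np.ndarray:
    """Encode an already-validated residue string to a uint8 code array."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 ranks for every length-k window of ``codes``.

    Returns ``(hashes, valid)`` where ``valid[i]`` is False for windows
    containing an N; the hash at an invalid position is meaningless.
    Horner evaluation: k passes over the array, no per-window Python work.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes64 = codes.astype(np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        h <<= np.uint64(2)
        h += codes64[j : j + n]
    bad = np.concatenate(([0], np.cumsum(codes >= CODE_N, dtype=np.int32)))
    valid = (bad[k:] - bad[:-k]) == 0
    return h, valid
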
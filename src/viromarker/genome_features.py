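"""Structural characterization of a candidate viral contig.

Assemblers emit circular genomes as linear contigs whose two ends carry an
identical copy of the same sequence — a direct terminal repeat (DTR). The
detector below finds the longest exact prefix that recurs as the suffix of
the contig (a "border" in string terms), capped at half the contig length so
a homopolymer cannot report itself as its own repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seqcodes
from .io_core import SequenceRecord


@dataclass(frozen=True)
class DtrResult:
    repeat_length: int
    prefix_start: int
    suffix_start: int
    is_circular_candidate: bool


def _border_lengths(codes: np.ndarray) -> list[int]:
    """All lengths L>0 with prefix(L) == suffix(L), via the KMP prefix chain."""
    s = codes.tolist()  # plain-int access is much faster than numpy scalars here
    n = len(s)
    pi = [0] * n
    k = 0
    for i in range(1, n):
        c = s[i]
        while k and s[k] != c:
            k = pi[k - 1]
        if s[k] == c:
            k += 1
        pi[i] = k
    borders = []
    b = pi[n - 1]
    while b > 0:
        borders.append(b)
        b = int(pi[b - 1])
    return borders


def detect_terminal_repeat(contig: SequenceRecord, min_len: int = 20) -> DtrResult:
    """Longest exact direct terminal repeat of length >= min_len.

    The repeat length is the largest L with min_len <= L <= len//2 such that
    the first and last L bases are identical; 0 if no such L exists.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n = len(contig)
    if n < 2 * min_len:
        raise ValueError(
            f"contig {contig.id!r} ({n} bp) shorter than 2*min_len ({2 * min_len})"
        )
    codes = _seqcodes.encode(contig.residues)
    repeat = 0
    for b in _border_lengths(codes):
        if b <= n // 2:
            repeat = b if b >= min_len else 0
            break
    circular = repeat >= min_len
    return DtrResult(
        repeat_length=repeat,
        prefix_start=0,
        suffix_start=n - repeat if repeat else 0,
        is_circular_candidate=circular,
    )


def gc_content(seq: SequenceRecord) -> float:
    """G+C fraction over non-N residues; errors on an all-N sequence."""
    codes = _seqcodes.encode(seq.residues)
    counts = np.bincount(codes, minlength=5)
    acgt = int(counts[:4].sum())
    if acgt == 0:
        raise ValueError(f"sequence {seq.id!r} has no A/C/G/T residues")
    return float(counts[1] + counts[2]) / acgt
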
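"""Oligonucleotide composition signal for virus-host prediction.

Viruses tend to ameliorate their oligonucleotide usage toward their host's,
so the Pearson correlation between the tetramer relative-frequency vectors
of a viral genome and a candidate host genome carries a (weak) host signal.
The null model shuffles the host genome: the shuffle keeps length and
mononucleotide content but destroys higher-order composition, so the real
correlation should exceed the shuffled mean when the signal is genuine.

Counting is single-strand, sliding window of step 1; windows containing an
N are skipped. k-mers are indexed in lexicographic order with A<C<G<T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _seqcodes
from .io_core import SequenceRecord


@dataclass(frozen=True)
class KmerProfile:
    k: int
    counts: np.ndarray  # int64, length 4**k, lexicographic order
    total: int
    source_id: str

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.total


@dataclass(frozen=True)
class NullSummary:
    correlations: list[float]
    mean: float
    n_shuffles: int
    seed: int


class DegenerateProfileError(ValueError):
    """Raised when a correlation input has zero variance."""


def _revcomp_ranks(k: int) -> np.ndarray:
    """Permutation mapping each k-mer rank to its reverse complement's rank."""
    idx = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(idx)
    tmp = idx.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def count_kmers(seq: SequenceRecord, k: int, canonical: bool = False) -> KmerProfile:
    """Count all 4**k k-mers of the given strand of ``seq``.

    With ``canonical=True`` the reverse-complement strand is counted too
    (each rank accumulates its own and its reverse complement's windows),
    the convention strand-agnostic k-mer counters use.
    """
    if len(seq) < k:
        raise ValueError(f"sequence {seq.id!r} shorter than k={k}")
    codes = _seqcodes.encode(seq.residues)
    hashes, valid = _seqcodes.kmer_hashes(codes, k)
    counts = np.bincount(hashes[valid].astype(np.int64), minlength=4**k)
    if canonical:
        counts = counts + counts[_revcomp_ranks(k)]
    return KmerProfile(k=k, counts=counts, total=int(counts.sum()), source_id=seq.id)


def profile_correlation(p: KmerProfile, q: KmerProfile) -> float:
    """Pearson correlation of the two relative-frequency vectors.

    Frequencies (not raw counts) make a ~68 kb virus comparable with a
    multi-megabase host; on frequencies the statistic is invariant to the
    totals, and Pearson on counts of equal totals would give the same r.
    """
    if p.k != q.k:
        raise ValueError(f"k mismatch: {p.k} vs {q.k}")
    if p.total <= 0 or q.total <= 0:
        raise ValueError("profiles must have positive totals")
    fp, fq = p.frequencies, q.frequencies
    if np.ptp(fp) == 0 or np.ptp(fq) == 0:
        raise DegenerateProfileError(
            f"zero-variance k-mer frequency vector ({p.source_id!r} vs {q.source_id!r})"
        )
    return float(stats.pearsonr(fp, fq).statistic)


def shuffle_sequence(seq: SequenceRecord, seed: int) -> SequenceRecord:
    """Uniform random permutation of the residues (same length and content)."""
    if len(seq) == 0:
        raise ValueError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(seed)
    codes = rng.permutation(_seqcodes.encode(seq.residues))
    return SequenceRecord(id=f"{seq.id}|shuffled", residues=_seqcodes.decode(codes))


def kmer_null_comparison(
    virus: SequenceRecord,
    host: SequenceRecord,
    k: int = 4,
    n_shuffles: int = 3,
    seed: int = 0,
    canonical: bool = False,
) -> tuple[float, NullSummary]:
    """Real virus-host k-mer correlation against a shuffled-host null.

    Returns ``(r_real, null)`` where the null holds the correlations of the
    virus profile against ``n_shuffles`` independent shuffles of the host.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    pv = count_kmers(virus, k, canonical)
    r_real = profile_correlation(pv, count_kmers(host, k, canonical))
    rng = np.random.default_rng(seed)
    null_rs = []
    for _ in range(n_shuffles):
        shuf = shuffle_sequence(host, int(rng.integers(2**31)))
        null_rs.append(profile_correlation(pv, count_kmers(shuf, k, canonical)))
    null = NullSummary(
        correlations=null_rs,
        mean=float(np.mean(null_rs)),
        n_shuffles=n_shuffles,
        seed=seed,
    )
    return r_real, null
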
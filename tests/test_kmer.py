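import itertools

import numpy as np
import pytest

from conftest import random_record
from viromarker.io_core import SequenceRecord
from viromarker.kmer import (
    DegenerateProfileError,
    KmerProfile,
    count_kmers,
    kmer_null_comparison,
    profile_correlation,
    shuffle_sequence,
)
from viromarker.simulate import CompositionModel, generate_genome


def brute_force_counts(residues: str, k: int) -> dict[str, int]:
    """Independent dictionary-based window count (N windows skipped)."""
    counts: dict[str, int] = {}
    for i in range(len(residues) - k + 1):
        w = residues[i : i + k]
        if "N" not in w:
            counts[w] = counts.get(w, 0) + 1
    return counts


def lexicographic_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


class TestCountKmers:
    @pytest.mark.parametrize(
        "residues,k,expected,total",
        [
            ("ACGTACGT", 4, {"ACGT": 2, "CGTA": 1, "GTAC": 1, "TACG": 1}, 5),
            ("AAAA", 4, {"AAAA": 1}, 1),
            ("ACNGT", 2, {"AC": 1, "GT": 1}, 2),  # windows CN, NG skipped
        ],
    )
    def test_known_profiles(self, residues, k, expected, total):
        profile = count_kmers(SequenceRecord(id="x", residues=residues), k)
        assert profile.total == total
        kmers = lexicographic_kmers(k)
        observed = {kmers[i]: int(c) for i, c in enumerate(profile.counts) if c}
        assert observed == expected

    def test_canonical_counting_is_strand_agnostic(self, rng):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(10):
            s = random_record(rng, int(rng.integers(50, 400)))
            rc = SequenceRecord(id="rc", residues="".join(comp[c] for c in reversed(s.residues)))
            k = int(rng.integers(1, 5))
            fwd = count_kmers(s, k, canonical=True)
            rev = count_kmers(rc, k, canonical=True)
            assert np.array_equal(fwd.counts, rev.counts)
            # canonical = own strand + reverse-complement strand
            both = count_kmers(s, k).counts + count_kmers(rc, k).counts
            assert np.array_equal(fwd.counts, both)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="shorter than k"):
            count_kmers(SequenceRecord(id="x", residues="ACG"), 4)

    def test_agrees_with_brute_force_on_random_sequences(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 2000))
            residues = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            k = int(rng.integers(1, 6))
            profile = count_kmers(SequenceRecord(id="x", residues=residues), k)
            kmers = lexicographic_kmers(k)
            observed = {kmers[i]: int(c) for i, c in enumerate(profile.counts) if c}
            assert observed == brute_force_counts(residues, k)
            assert profile.total == sum(observed.values()) == int(profile.counts.sum())


def make_profile(freqs, total=1000, k=1, source="p") -> KmerProfile:
    counts = (np.asarray(freqs) * total).astype(np.int64)
    return KmerProfile(k=k, counts=counts, total=int(counts.sum()), source_id=source)


class TestProfileCorrelation:
    def test_self_correlation_is_one(self, rng):
        profile = count_kmers(random_record(rng, 500), 4)
        assert profile_correlation(profile, profile) == pytest.approx(1.0)

    def test_hand_computed_anticorrelated_mononucleotides(self):
        # (0.5,0.25,0.25,0) vs (0,0.25,0.25,0.5): deviations from the mean
        # are exactly opposite, so Pearson r = -1
        p = make_profile([0.5, 0.25, 0.25, 0.0])
        q = make_profile([0.0, 0.25, 0.25, 0.5])
        assert profile_correlation(p, q) == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_reverse_complement(self, rng):
        s = random_record(rng, 800)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = SequenceRecord(id="rc", residues="".join(comp[c] for c in reversed(s.residues)))
        p, q = count_kmers(s, 3), count_kmers(rc, 3)
        x, y = p.frequencies, q.frequencies
        r_oracle = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert profile_correlation(p, q) == pytest.approx(r_oracle, abs=1e-12)

    def test_symmetric_and_total_invariant(self, rng):
        p = count_kmers(random_record(rng, 300, "a"), 2)
        q = count_kmers(random_record(rng, 700, "b"), 2)
        assert profile_correlation(p, q) == pytest.approx(profile_correlation(q, p))
        scaled = KmerProfile(k=q.k, counts=q.counts * 7, total=q.total * 7, source_id="b7")
        assert profile_correlation(p, scaled) == pytest.approx(profile_correlation(p, q))

    def test_k_mismatch_and_degenerate_flagged(self, rng):
        p = count_kmers(random_record(rng, 100), 2)
        q = count_kmers(random_record(rng, 100), 3)
        with pytest.raises(ValueError, match="k mismatch"):
            profile_correlation(p, q)
        flat = make_profile([0.25, 0.25, 0.25, 0.25])
        with pytest.raises(DegenerateProfileError):
            profile_correlation(flat, flat)


class TestShuffle:
    def test_residue_multiset_conserved(self, rng):
        for _ in range(20):
            s = random_record(rng, int(rng.integers(1, 500)))
            out = shuffle_sequence(s, int(rng.integers(2**31)))
            assert sorted(out.residues) == sorted(s.residues)

    def test_single_permutation_class(self):
        assert shuffle_sequence(SequenceRecord(id="x", residues="AAAA"), 3).residues == "AAAA"

    def test_deterministic_per_seed(self, rng):
        s = random_record(rng, 200)
        assert shuffle_sequence(s, 11).residues == shuffle_sequence(s, 11).residues
        assert shuffle_sequence(s, 11).residues != shuffle_sequence(s, 12).residues


class TestNullComparison:
    def test_identical_genomes_beat_their_null(self, rng):
        genome = random_record(rng, 2000)
        r_real, null = kmer_null_comparison(genome, genome, k=4, n_shuffles=1, seed=5)
        assert r_real == pytest.approx(1.0)
        assert null.correlations[0] < 1.0

    def test_reproducible_for_fixed_seed(self, rng):
        v, h = random_record(rng, 1000, "v"), random_record(rng, 1500, "h")
        _, null_a = kmer_null_comparison(v, h, n_shuffles=3, seed=42)
        _, null_b = kmer_null_comparison(v, h, n_shuffles=3, seed=42)
        assert null_a.correlations == null_b.correlations
        assert null_a.mean == pytest.approx(np.mean(null_a.correlations))
        assert null_a.n_shuffles == 3

    def test_shared_composition_recovered_against_decoy_and_null(self):
        """Virus and true host from one order-3 model, decoy from another:
        the real correlation should beat both the decoy and the shuffled
        null in nearly every seeded replicate."""
        wins = 0
        n_trials = 30
        for seed in range(n_trials):
            shared = CompositionModel.random_skewed(order=3, seed=1000 + seed)
            other = CompositionModel.random_skewed(order=3, seed=5000 + seed)
            virus = generate_genome(8000, shared, seed=3 * seed, genome_id="v")
            host = generate_genome(12000, shared, seed=3 * seed + 1, genome_id="h")
            decoy = generate_genome(12000, other, seed=3 * seed + 2, genome_id="d")
            r_host, null = kmer_null_comparison(virus, host, k=4, n_shuffles=3, seed=seed)
            r_decoy, _ = kmer_null_comparison(virus, decoy, k=4, n_shuffles=1, seed=seed)
            if r_host > r_decoy and r_host > null.mean:
                wins += 1
        assert wins >= 0.95 * n_trials
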
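import numpy as np
import pytest

from conftest import random_record
from viromarker.io_core import ReadPair, SequenceRecord
from viromarker.mapping import (
    Alignment,
    ReadBatch,
    compute_abundance,
    deduplicate,
    map_reads,
    taxon_abundance,
)
from viromarker.simulate import simulate_sample

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def mutate(rng, s: str, n_subs: int) -> str:
    out = list(s)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        out[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(out)


def brute_force_best(read: str, ref: str):
    """Best ungapped end-to-end placement over all diagonals and strands."""
    best = (-1.0, None, None)
    for strand, probe in (("+", read), ("-", revcomp(read))):
        for start in range(len(ref) - len(read) + 1):
            window = ref[start : start + len(read)]
            ident = sum(a == b for a, b in zip(window, probe)) / len(read)
            if ident > best[0]:
                best = (ident, start, strand)
    return best


def pair_at(ref: str, start: int, read_len=100, insert=250, read_id="r0"):
    frag = ref[start : start + insert]
    return ReadPair(read_id, frag[:read_len], revcomp(frag[-read_len:]))


class TestMapReads:
    def test_exact_substring_maps_at_origin(self, rng):
        ref = random_record(rng, 2000, "ref")
        read = ref.residues[200:350]
        alns = map_reads([ReadPair("r0", read, revcomp(ref.residues[400:550]))], ref)
        m1 = next(a for a in alns if a.mate == 1)
        assert (m1.ref_start, m1.strand, m1.identity) == (200, "+", 1.0)
        m2 = next(a for a in alns if a.mate == 2)
        assert (m2.ref_start, m2.strand, m2.identity) == (400, "-", 1.0)

    def test_identity_threshold_boundary(self, rng):
        ref = random_record(rng, 3000, "ref")
        site = ref.residues[500:650]  # 150 bp
        ok = mutate(rng, site, 3)     # identity 147/150 = 0.98
        bad = mutate(rng, site, 10)   # identity 140/150 ~ 0.933
        alns = map_reads([ReadPair("r0", ok, bad)], ref, min_identity=0.95)
        mates = {a.mate for a in alns}
        assert mates == {1}
        a = alns[0]
        oracle_ident, oracle_start, _ = brute_force_best(ok, ref.residues)
        assert a.identity == pytest.approx(oracle_ident)
        assert a.ref_start == oracle_start == 500

    def test_read_without_shared_seed_is_unmapped(self, rng):
        ref = random_record(rng, 5000, "ref")
        for _ in range(20):
            read = random_record(rng, 150, "x").residues
            ref_kmers = {ref.residues[i:i + 31] for i in range(len(ref) - 30)}
            read_kmers = {read[i:i + 31] for i in range(len(read) - 30)} | {
                revcomp(read)[i:i + 31] for i in range(len(read) - 30)
            }
            if ref_kmers & read_kmers:  # astronomically unlikely; skip if so
                continue
            assert map_reads([ReadPair("r0", read, read)], ref) == []
            break

    def test_every_error_free_sampled_read_maps(self, rng):
        ref = random_record(rng, 4000, "ref")
        pairs = [pair_at(ref.residues, int(rng.integers(0, 3750)), read_id=f"r{i}")
                 for i in range(200)]
        alns = map_reads(pairs, ref)
        assert len(alns) == 400
        assert all(a.identity == 1.0 for a in alns)

    def test_percent_invariant_under_read_order(self, rng):
        ref = random_record(rng, 2000, "ref")
        pairs = [pair_at(ref.residues, int(rng.integers(0, 1700)), read_id=f"r{i}")
                 for i in range(50)]
        fwd = compute_abundance(map_reads(pairs, ref), 100, ref)
        rev = compute_abundance(map_reads(pairs[::-1], ref), 100, ref)
        assert fwd.percent_mapped == rev.percent_mapped
        assert fwd.mapped_reads_dedup == rev.mapped_reads_dedup

    def test_tiling_library_reaches_full_breadth(self, rng):
        ref = random_record(rng, 1000, "ref")
        pairs = [pair_at(ref.residues, s, read_len=100, insert=250, read_id=f"t{s}")
                 for s in range(0, 751, 50)]
        ab = compute_abundance(map_reads(pairs, ref), len(pairs) * 2, ref)
        assert ab.breadth == 1.0


class TestDeduplicate:
    @staticmethod
    def aln(read_id, mate, start, strand="+"):
        return Alignment(read_id=read_id, mate=mate, ref_id="ref", ref_start=start,
                         strand=strand, aligned_length=100, identity=1.0)

    def test_identical_pair_signature_removed(self):
        alns = [self.aln("a", 1, 10), self.aln("a", 2, 200, "-"),
                self.aln("b", 1, 10), self.aln("b", 2, 200, "-")]
        out = deduplicate(alns)
        assert {a.read_id for a in out} == {"a"}

    def test_different_mate2_start_both_kept(self):
        alns = [self.aln("a", 1, 10), self.aln("a", 2, 200),
                self.aln("b", 1, 10), self.aln("b", 2, 210)]
        assert {a.read_id for a in deduplicate(alns)} == {"a", "b"}

    def test_pcr_duplicated_library_recovers_unique_count(self, rng):
        ref = random_record(rng, 40_000, "ref")
        pairs, truth = simulate_sample(
            [(ref, 1.0)], n_pairs=2000, duplicate_rate=0.2, error_rate=0.0, seed=9
        )
        alns = map_reads(pairs, ref)
        deduped = deduplicate(alns)
        n_unique_pairs = truth["pairs"]["ref"]
        # coordinate collisions between distinct fragments are possible but
        # rare on a 40 kb reference; allow a small margin
        assert abs(len(deduped) / 2 - n_unique_pairs) <= 0.01 * n_unique_pairs


class TestComputeAbundance:
    def test_percent_arithmetic(self, rng):
        ref = random_record(rng, 1000, "ref")
        alns = [TestDeduplicate.aln(f"r{i}", 1, i) for i in range(84)]
        ab = compute_abundance(alns, 1000, ref)
        assert ab.percent_mapped == pytest.approx(8.4)

    def test_breadth_from_depth_vector(self):
        ref = SequenceRecord(id="ref", residues="ACGT")
        alns = [
            Alignment("a", 1, "ref", 0, "+", 1, 1.0),
            Alignment("b", 1, "ref", 2, "+", 2, 1.0),
            Alignment("c", 1, "ref", 3, "+", 1, 1.0),
            Alignment("d", 1, "ref", 3, "-", 1, 1.0),
        ]
        ab = compute_abundance(alns, 10, ref)
        assert ab.breadth == 0.75  # depth (1,0,1,3): 3 of 4 positions covered

    def test_zero_mapped_reads(self, rng):
        ref = random_record(rng, 100, "ref")
        ab = compute_abundance([], 500, ref)
        assert ab.percent_mapped == 0.0 and ab.breadth == 0.0

    def test_zero_library_rejected(self, rng):
        with pytest.raises(ValueError, match="library_size"):
            compute_abundance([], 0, random_record(rng, 100, "ref"))


class TestTaxonAbundance:
    def test_recovers_planted_mixture(self, rng):
        host_a = random_record(rng, 30_000, "A")
        host_b = random_record(rng, 30_000, "B")
        pairs, _ = simulate_sample(
            [(host_a, 0.9), (host_b, 0.1)], n_pairs=5000, error_rate=0.0, seed=4
        )
        table = taxon_abundance(pairs, [host_a, host_b]).set_index("taxon")
        assert table.loc["A", "percent_of_library"] == pytest.approx(90, abs=1.0)
        assert table.loc["B", "percent_of_library"] == pytest.approx(10, abs=1.0)

    def test_tie_between_references_unassigned(self, rng):
        genome = random_record(rng, 2000, "A")
        clone = SequenceRecord(id="B", residues=genome.residues)
        read = genome.residues[100:250]
        table = taxon_abundance([ReadPair("r0", read, revcomp(read))], [genome, clone])
        assert int(table["raw_reads"].sum()) == 0

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError, match="at least one reference"):
            taxon_abundance([], [])
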
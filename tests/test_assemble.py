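"""K-mer baiting, read mapping/extension, iterative assembly, read budget."""

import numpy as np
import pytest

from mitoskim._seq import canonical, revcomp
from mitoskim.assemble import (
    AssemblyParams,
    Contig,
    bait_reads,
    build_kmer_index,
    estimate_required_read_pairs,
    find_terminal_overlap,
    iterative_assemble,
    map_and_extend,
)
from mitoskim.formats_io import ReadPair, SeqRecord
from mitoskim.simulate import SimConfig, make_bait, simulate_mitogenome, simulate_reads
from conftest import rotation_of


def _pair(seq1, seq2=None, rid="p0"):
    seq2 = seq2 or revcomp(seq1)
    return ReadPair(rid, seq1, seq2, [40] * len(seq1), [40] * len(seq2))


class TestKmerIndex:
    def test_hand_enumerated_kmers(self):
        # ACGTACGTACGT has two 11-mers: positions 0 and 1
        read = "ACGTACGTACGT"
        idx = build_kmer_index([_pair(read, read)], k=11)
        expected = {canonical(read[0:11]), canonical(read[1:12])}
        assert set(idx.index) == expected

    def test_all_n_read_contributes_nothing(self):
        idx = build_kmer_index([_pair("N" * 30, "ACGTACGTACGTACG")], k=11)
        for postings in idx.index.values():
            assert all(mate == 2 for _, mate in postings)

    def test_read_and_revcomp_share_entries(self):
        read = "ACGGTTACGGATCCAGGTTACAGGATTACCA"
        idx1 = build_kmer_index([_pair(read, read)], k=21)
        idx2 = build_kmer_index([_pair(revcomp(read), revcomp(read))], k=21)
        assert set(idx1.index) == set(idx2.index)

    def test_k_longer_than_reads_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_kmer_index([_pair("ACGTACGTACGTACG")], k=31)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_index([_pair("A" * 40)], k=20)


class TestBaitReads:
    def test_query_identical_to_read_recruits_pair(self):
        rng = np.random.default_rng(0)
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        idx = build_kmer_index([_pair(read, read)], k=31)
        assert bait_reads(idx, read, 2) == {0}

    def test_unrelated_query_recruits_nothing(self):
        idx = build_kmer_index([_pair("ACGT" * 20)], k=31)
        assert bait_reads(idx, "TTGA" * 20, 2) == set()

    def test_matches_brute_force_at_two_percent_divergence(self):
        rng = np.random.default_rng(17)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        # reads from a 2%-diverged relative of the query
        diverged = list(genome)
        for pos in rng.choice(3000, 60, replace=False):
            diverged[pos] = "ACGT"[int(rng.integers(4))]
        diverged = "".join(diverged)
        pairs = []
        for i in range(80):
            s = int(rng.integers(0, 3000 - 300))
            pairs.append(
                _pair(diverged[s : s + 150], revcomp(diverged[s + 150 : s + 300]), f"p{i}")
            )
        k, min_shared = 31, 2
        idx = build_kmer_index(pairs, k=k)
        got = bait_reads(idx, genome, min_shared)

        query_kmers = {canonical(genome[i : i + k]) for i in range(len(genome) - k + 1)}
        expected = set()
        for pi, p in enumerate(pairs):
            for mate in (p.mate1_seq, p.mate2_seq):
                mers = {canonical(mate[i : i + k]) for i in range(len(mate) - k + 1)}
                if len(mers & query_kmers) >= min_shared:
                    expected.add(pi)
                    break
        assert got == expected
        assert len(got) > 0


class TestMapAndExtend:
    def _tiling_setup(self):
        rng = np.random.default_rng(23)
        contig_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        reads = [
            _pair(contig_seq[s : s + 100], revcomp(contig_seq[s : s + 100]), f"t{s}")
            for s in range(0, 301, 50)
        ]
        return contig_seq, reads

    def test_exact_tiling_reads_leave_contig_unchanged(self):
        contig_seq, reads = self._tiling_setup()
        new, n_mapped = map_and_extend(Contig(seq=contig_seq), reads, AssemblyParams())
        assert new.seq == contig_seq
        assert n_mapped == 2 * len(reads)

    def test_five_overhanging_reads_extend_thirty_nt(self):
        rng = np.random.default_rng(29)
        full = "".join("ACGT"[i] for i in rng.integers(0, 4, 430))
        contig_seq = full[:400]
        over = full[300:430]  # 30 nt beyond the 3' end
        interior = revcomp(full[0:100])  # mate 2 maps inside the contig
        reads = [_pair(over, interior, f"o{i}") for i in range(5)]
        new, _ = map_and_extend(Contig(seq=contig_seq), reads, AssemblyParams())
        assert new.seq == full

    def test_two_overhanging_reads_below_threshold_do_not_extend(self):
        rng = np.random.default_rng(31)
        full = "".join("ACGT"[i] for i in rng.integers(0, 4, 430))
        contig_seq = full[:400]
        over = full[300:430]
        interior = revcomp(full[0:100])
        reads = [_pair(over, interior, f"o{i}") for i in range(2)]
        new, _ = map_and_extend(
            Contig(seq=contig_seq), reads, AssemblyParams(min_extend_cov=3)
        )
        assert new.seq == contig_seq


class TestIterativeAssemble:
    def test_identity_bait_error_free_exact_recovery(self, clean_truth, clean_reads):
        state = iterative_assemble(
            clean_reads, clean_truth.genome, AssemblyParams(rng_seed=5)
        )
        g = clean_truth.genome.seq
        assert state.iteration <= 2
        assert state.circularized
        assert len(state.contig) == len(g)
        assert state.contig.seq in g + g  # equal up to rotation

    def test_diverged_bait_noisy_reads_high_identity(self, insect_truth, insect_reads, insect_bait, insect_cfg):
        state = iterative_assemble(
            insect_reads, insect_bait, AssemblyParams(rng_seed=7)
        )
        assert state.circularized
        assert len(state.contig) == insect_cfg.genome_len
        rot = rotation_of(state.contig.seq, insect_truth.genome.seq)
        assert rot is not None
        identity = sum(a == b for a, b in zip(state.contig.seq, rot)) / len(rot)
        assert identity >= 0.999

    def test_linear_genome_not_circularized(self):
        cfg = SimConfig(rng_seed=4, genome_len=6000, coverage=40, circular=False)
        truth = simulate_mitogenome(cfg)
        pairs = simulate_reads(truth, cfg)
        state = iterative_assemble(pairs, make_bait(truth, cfg), AssemblyParams(rng_seed=4))
        assert not state.circularized
        assert state.converged

    def test_unrelated_bait_raises(self, clean_reads):
        stranger = SeqRecord(id="x", seq="ACGT" * 500)
        with pytest.raises(ValueError, match="bait too divergent"):
            iterative_assemble(clean_reads, stranger, AssemblyParams())

    def test_deterministic_under_fixed_seed(self, small_truth, small_reads, small_cfg):
        bait = make_bait(small_truth, small_cfg)
        s1 = iterative_assemble(small_reads, bait, AssemblyParams(rng_seed=3))
        s2 = iterative_assemble(small_reads, bait, AssemblyParams(rng_seed=3))
        assert s1.contig.seq == s2.contig.seq
        assert s1.contig.tallies == s2.contig.tallies

    def test_terminal_overlap_found_and_verified(self):
        rng = np.random.default_rng(37)
        core = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        seq = core + core[:80]  # 80 nt duplicated overlap
        assert find_terminal_overlap(seq, 50, 0.99) == 80
        assert find_terminal_overlap(core, 50, 0.99) == 0


class TestReadBudget:
    @pytest.mark.parametrize(
        "mito_len,frac,read_len,cov,expected",
        [
            (15000, 0.01, 150, 100, 500_000),
            (15000, 1.0, 150, 1, 50),
            (15000, 0.01, 150, 200, 1_000_000),  # doubling cov doubles pairs
        ],
    )
    def test_pair_estimates(self, mito_len, frac, read_len, cov, expected):
        assert estimate_required_read_pairs(mito_len, frac, read_len, cov) == expected

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            estimate_required_read_pairs(15000, 0.0, 150, 100)
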
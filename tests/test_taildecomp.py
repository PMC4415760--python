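import numpy as np
import pytest

from mirtail import mapper, refio, taildecomp
from mirtail.taildecomp import decompose, assign, build_matrix, MirnaVariant

from conftest import brute_force_decompose


class TestDecompose:
    def test_full_map_zero_trim(self, toy_genome, toy_index):
        read = toy_genome.fetch("chr1", 10, 31)
        ht = decompose(read, toy_index)
        assert ht.status == "mapped_full"
        assert (ht.head, ht.tail) == (read, "")

    def test_tailed_read_splits_at_longest_head(self, toy_mature, toy_index):
        # the flank downstream of the mature locus is C/G-only, so a
        # 2-nt T tail cannot be templated
        read = toy_mature[:19] + "TT"
        ht = decompose(read, toy_index)
        assert ht.status == "decomposed"
        assert (ht.head, ht.tail) == (toy_mature[:19], "TT")
        assert ht.head + ht.tail == read

    def test_unmappable_read(self, toy_index):
        ht = decompose("T" * 18, toy_index, min_head=15)
        assert ht.status == "unassignable"
        assert ht.hits == ()

    def test_too_short_read_rejected(self, toy_index):
        with pytest.raises(ValueError, match="min_head"):
            decompose("ACGTACGTAC", toy_index, min_head=15)

    def test_maximality_matches_brute_force(self, sim_reference, sim_index):
        """Property: decompose() equals the exhaustive longest-mapping-prefix
        oracle for random reads of every flavor."""
        rng = np.random.default_rng(5)
        g = sim_reference.genome
        seq = g.sequences["chr1"]
        matures = [a.mature_seq for a in sim_reference.annotations]
        for trial in range(200):
            kind = trial % 4
            if kind == 0:  # exact genomic
                i = int(rng.integers(0, len(seq) - 21))
                read = seq[i:i + 21]
            elif kind == 1:  # genomic + tail
                i = int(rng.integers(0, len(seq) - 20))
                read = seq[i:i + 20] + "".join(
                    rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            elif kind == 2:  # truncated mature + U tail
                m = matures[int(rng.integers(0, len(matures)))]
                t = int(rng.integers(0, 4))
                read = m[:len(m) - t] + "T" * int(rng.integers(0, 4))
                if len(read) < 15:
                    continue
            else:  # random, usually unmappable
                read = "".join(rng.choice(list("ACGT"), size=18))
            ht = decompose(read, sim_index)
            oracle_len, oracle_status = brute_force_decompose(read, g)
            assert ht.status == oracle_status
            if oracle_len is not None:
                assert len(ht.head) == oracle_len
                assert ht.head + ht.tail == read


class TestAssign:
    def test_exact_mature_is_origin_cell(self, toy_index, toy_annotation):
        ht = decompose(toy_annotation.mature_seq, toy_index)
        (v,) = assign(ht, [toy_annotation])
        assert (v.truncation, v.tail_len) == (0, 0)

    def test_truncated_and_tailed_variant(self, toy_index, toy_annotation):
        # 1-nt truncation + 1-nt U tail: the (1,1) species
        read = toy_annotation.mature_seq[:19] + "T"
        ht = decompose(read, toy_index)
        (v,) = assign(ht, [toy_annotation])
        assert (v.truncation, v.tail_len) == (1, 1)
        assert v.tail_seq == "T"

    def test_templated_extension_negative_truncation(self, toy_genome,
                                                     toy_index,
                                                     toy_annotation):
        read = toy_genome.fetch("chr1", 10, 31)  # mature + 1 templated nt
        ht = decompose(read, toy_index)
        (v,) = assign(ht, [toy_annotation])
        assert v.truncation == -1
        m = build_matrix([v], "miR-toy")
        assert m.cells == {} and m.excluded == {-1: 1}

    def test_five_prime_shifted_head_not_assigned(self, toy_genome, toy_index,
                                                  toy_annotation):
        read = toy_genome.fetch("chr1", 11, 30)  # starts 1 nt downstream
        ht = decompose(read, toy_index)
        assert ht.status == "mapped_full"
        assert assign(ht, [toy_annotation]) == []

    def test_multi_annotation_full_count_each(self, toy_index, toy_genome,
                                              toy_annotation):
        twin = refio.MirnaAnnotation("miR-twin", "chr1", "+", 10, 30,
                                     toy_annotation.mature_seq)
        ht = decompose(toy_annotation.mature_seq, toy_index)
        variants = assign(ht, [toy_annotation, twin], count=7)
        assert sorted(v.mirna_id for v in variants) == ["miR-toy", "miR-twin"]
        assert all(v.count == 7 for v in variants)


class TestMatrix:
    def test_aggregation_fixture(self):
        variants = (
            [MirnaVariant("m", 0, "", 60)]
            + [MirnaVariant("m", 0, "T", 20)]
            + [MirnaVariant("m", 1, "", 15)]
            + [MirnaVariant("m", 1, "T", 5)]
        )
        m = build_matrix(variants, "m")
        assert m.cells == {(0, 0): 60, (0, 1): 20, (1, 0): 15, (1, 1): 5}
        assert m.total == 100

    def test_equal_length_tails_share_cell_with_breakdown(self):
        m = build_matrix([MirnaVariant("m", 0, "TT", 4),
                          MirnaVariant("m", 0, "TA", 6)], "m")
        assert m.cells == {(0, 2): 10}
        assert m.tails[(0, 2)] == {"TT": 4, "TA": 6}

    def test_empty_matrix(self):
        m = build_matrix([], "m")
        assert m.cells == {} and m.total == 0

    def test_mixed_mirna_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            build_matrix([MirnaVariant("other", 0, "", 1)], "m")

    def test_conservation_cells_plus_excluded(self):
        m = build_matrix([MirnaVariant("m", 0, "", 3),
                          MirnaVariant("m", -1, "", 2),
                          MirnaVariant("m", 2, "TT", 4)], "m")
        assert m.total + m.total_excluded == 9


class TestProfileLibrary:
    def test_reconstruction_and_accounting(self, sim_reference, sim_index):
        from mirtail import simdata

        reads, truth = simdata.simulate_library(
            simdata.hen1_regime(), sim_reference, 1500, seed=21)
        profile = taildecomp.profile_library(reads, sim_index,
                                             sim_reference.annotations)
        for seq, ht in profile.headtails.items():
            if ht.status != "unassignable":
                assert ht.head + ht.tail == seq
        assert (profile.n_mapped_full + profile.n_decomposed
                + profile.n_unassignable) == reads.total_retained
        # simulated truth is recovered cell by cell
        for ann in sim_reference.annotations:
            assert dict(profile.matrices[ann.mirna_id].cells) == dict(
                truth.observed(ann.mirna_id))
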
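"""Anchoring, chaining and region classification, including the truth-log
oracle on simulated pairs and the small-genome DP cross-check."""

import numpy as np
import pytest

import edlib

from straindiff import regions as reg
from straindiff.genome import AnnotatedGenome, Feature, revcomp
from straindiff.simulate import AncestorSpec, EventSpec, evolve_pair, \
    generate_ancestor
from straindiff.sequtils import decode, random_sequence


def _random_seq(n, seed):
    return decode(random_sequence(n, 0.5, np.random.default_rng(seed)))


class TestFindAnchors:
    def test_identical_sequences_single_full_length_anchor(self):
        s = _random_seq(10_000, 0)
        anchors = reg.find_anchors(s, s, 20)
        plus = [a for a in anchors if a.strand == "+"]
        assert len(plus) == 1
        assert plus[0].a_start == 0 and plus[0].length == len(s)

    def test_reverse_complement_single_minus_anchor(self):
        s = _random_seq(10_000, 1)
        anchors = reg.find_anchors(s, revcomp(s), 20)
        minus = [a for a in anchors if a.strand == "-"]
        assert len(minus) == 1
        assert minus[0].length == len(s)
        assert minus[0].b_start == 0

    def test_unrelated_sequences_expected_zero_anchors(self):
        # P(any shared 20-mer) <= 2 L^2 4^-20 ~ 2e-4 for L = 10 kb
        a, b = _random_seq(10_000, 2), _random_seq(10_000, 3)
        assert reg.find_anchors(a, b, 20) == []

    def test_anchor_substrings_match_exactly(self):
        s = _random_seq(5000, 4)
        t = s[:2000] + _random_seq(500, 5) + s[2000:]
        for a in reg.find_anchors(s, t, 20):
            sub_a = s[a.a_start:a.a_end]
            sub_b = t[a.b_start:a.b_end]
            if a.strand == "-":
                sub_b = revcomp(sub_b)
            assert sub_a == sub_b

    def test_k_min_floor_enforced(self):
        with pytest.raises(ValueError, match="k_min"):
            reg.find_anchors("ACGT" * 10, "ACGT" * 10, 8)


class TestChainAnchors:
    def test_collinear_anchors_single_block(self):
        s = _random_seq(20_000, 6)
        anchors = reg.find_anchors(s, s, 20)
        blocks = reg.chain_anchors(anchors, s, s)
        assert len(blocks) == 1
        assert blocks[0].on_main_chain
        assert blocks[0].a_interval == (0, len(s))

    def test_displaced_cluster_becomes_translocated_block(self):
        # a 5 kbp homologous cluster displaced by +50 kbp in genome A
        core = _random_seq(60_000, 7)
        moved = core[10_000:15_000]
        seq_b = core
        seq_a = core[:10_000] + core[15_000:55_000] + moved + core[55_000:]
        anchors = reg.find_anchors(seq_a, seq_b, 20)
        blocks = reg.chain_anchors(anchors, seq_a, seq_b)
        off = [b for b in blocks if not b.on_main_chain]
        assert len(off) == 1
        a0, a1 = off[0].a_interval
        b0, b1 = off[0].b_interval
        assert abs(a0 - 50_000) <= 40 and abs(a1 - 55_000) <= 40
        assert abs(b0 - 10_000) <= 40 and abs(b1 - 15_000) <= 40

    def test_empty_anchor_list_gives_no_blocks(self):
        assert reg.chain_anchors([], "ACGT", "ACGT") == []


class TestSegmentAndClassify:
    def test_identical_genomes_single_collinear_region(self):
        seq = _random_seq(20_000, 8)
        g = AnnotatedGenome("g", seq, [Feature("f1", "CDS", 100, 400,
                                               protein="M" * 99)])
        anchors = reg.find_anchors(seq, seq, 20)
        blocks = reg.chain_anchors(anchors, seq, seq)
        calls = reg.segment_and_classify(blocks, g, g)
        assert len(calls) == 1
        assert calls[0].region_class == "collinear"
        assert calls[0].a_interval == (0, len(seq))
        assert calls[0].b_interval == (0, len(seq))

    def test_overlapping_blocks_raise(self):
        g = AnnotatedGenome("g", "A" * 1000)
        blocks = [reg.AlignmentBlock((0, 500), (0, 500)),
                  reg.AlignmentBlock((400, 900), (500, 1000))]
        with pytest.raises(ValueError, match="overlapping"):
            reg.segment_and_classify(blocks, g, g)

    def test_truth_log_oracle_on_simulated_pair(self, evolved_pair):
        a, b, log = evolved_pair
        anchors = reg.find_anchors(a.sequence, b.sequence, 20)
        blocks = reg.chain_anchors(anchors, a.sequence, b.sequence)
        calls = reg.segment_and_classify(blocks, a, b)
        counts = reg.class_counts(calls)
        expected = log.expected_region_counts()
        for key in ("exclusive_A", "exclusive_B", "divergent", "translocated"):
            assert counts[key] == expected[key], key

    def test_partition_covers_both_genomes(self, evolved_pair):
        a, b, _ = evolved_pair
        anchors = reg.find_anchors(a.sequence, b.sequence, 20)
        blocks = reg.chain_anchors(anchors, a.sequence, b.sequence)
        calls = reg.segment_and_classify(blocks, a, b)
        for genome, label in ((a, "A"), (b, "B")):
            ivs = sorted(r.interval(label) for r in calls if r.interval(label))
            assert ivs[0][0] == 0
            assert ivs[-1][1] == len(genome)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 == s2  # disjoint and gap-free

    def test_swap_symmetry(self, evolved_pair):
        a, b, _ = evolved_pair
        anchors = reg.find_anchors(a.sequence, b.sequence, 20)
        blocks = reg.chain_anchors(anchors, a.sequence, b.sequence)
        fwd = reg.class_counts(reg.segment_and_classify(blocks, a, b))
        anchors_r = reg.find_anchors(b.sequence, a.sequence, 20)
        blocks_r = reg.chain_anchors(anchors_r, b.sequence, a.sequence)
        rev = reg.class_counts(reg.segment_and_classify(blocks_r, b, a))
        assert fwd["exclusive_A"] == rev["exclusive_B"]
        assert fwd["exclusive_B"] == rev["exclusive_A"]
        assert fwd["divergent"] == rev["divergent"]
        assert fwd["translocated"] == rev["translocated"]

    def test_exclusive_class_requires_a_feature(self):
        # featureless inserted sequence is merged into collinear, not called
        seq = _random_seq(20_000, 9)
        ins = _random_seq(800, 10)
        seq_a = seq[:10_000] + ins + seq[10_000:]
        ga = AnnotatedGenome("a", seq_a)
        gb = AnnotatedGenome("b", seq)
        anchors = reg.find_anchors(seq_a, seq, 20)
        blocks = reg.chain_anchors(anchors, seq_a, seq)
        calls = reg.segment_and_classify(blocks, ga, gb)
        assert all(r.region_class != "exclusive" for r in calls)


class TestBoundaryAgreementWithDP:
    def test_block_boundaries_match_global_alignment(self):
        """On a small pair with one insertion, block boundaries agree with
        an independent dynamic-programming global alignment (edlib NW path)
        within 2 k_min."""
        k = 20
        base = _random_seq(12_000, 11)
        island = _random_seq(1500, 12)
        seq_a = base[:6000] + island + base[6000:]
        anchors = reg.find_anchors(seq_a, base, k)
        blocks = reg.chain_anchors(anchors, seq_a, base)
        main = [b for b in blocks if b.on_main_chain]
        assert len(main) == 2
        # DP oracle: the optimal edit distance equals the planted insertion
        # length, confirming there is no other homology structure
        res = edlib.align(seq_a, base, mode="NW", task="distance")
        assert res["editDistance"] == len(island)
        # block boundaries recover the planted junctions
        assert abs(main[0].a_interval[1] - 6000) <= 2 * k
        assert abs(main[1].a_interval[0] - (6000 + len(island))) <= 2 * k
        assert abs(main[0].b_interval[1] - 6000) <= 2 * k
        assert abs(main[1].b_interval[0] - 6000) <= 2 * k


class TestSummaries:
    def test_empty_region_list_gives_zero_summary(self):
        df = reg.summarize_regions([])
        assert (df["count"] == 0).all()
        assert (df["total_bp"] == 0).all()

    def test_mean_is_total_over_count(self, evolved_pair):
        a, b, _ = evolved_pair
        anchors = reg.find_anchors(a.sequence, b.sequence, 20)
        blocks = reg.chain_anchors(anchors, a.sequence, b.sequence)
        calls = reg.segment_and_classify(blocks, a, b)
        df = reg.summarize_regions(calls)
        nz = df[df["count"] > 0]
        assert np.allclose(nz["mean_bp"], nz["total_bp"] / nz["count"])


class TestIslandOverlap:
    def test_overlap_arithmetic(self):
        r = reg.RegionCall("R1", "exclusive", (99, 200), None, owner="A",
                           feature_ids_a=["f"])
        # region 100..200, island 150..400 (1-based) -> 51 bp overlap
        table, summary = reg.overlap_with_islands([r], [(149, 400)], [])
        assert table.iloc[0]["overlap_bp"] == 51
        assert summary["n_exclusive_with_island"] == 1

    def test_disjoint_sets_no_overlap(self):
        r = reg.RegionCall("R1", "exclusive", (0, 100), None, owner="A",
                           feature_ids_a=["f"])
        table, summary = reg.overlap_with_islands([r], [(500, 600)], [])
        assert table.empty and summary["n_exclusive_with_island"] == 0

    def test_insertion_derived_exclusives_overlap_their_islands(
            self, evolved_pair):
        a, b, log = evolved_pair
        anchors = reg.find_anchors(a.sequence, b.sequence, 20)
        blocks = reg.chain_anchors(anchors, a.sequence, b.sequence)
        calls = reg.segment_and_classify(blocks, a, b)
        islands_a = [e.a_interval for e in log.of_type("insertion")
                     if e.genome == "A"]
        islands_b = [e.b_interval for e in log.of_type("insertion")
                     if e.genome == "B"]
        table, _ = reg.overlap_with_islands(calls, islands_a, islands_b)
        # every island interval is hit by an exclusive region
        assert len(table) >= len(islands_a) + len(islands_b)

    def test_bad_island_interval_raises(self):
        with pytest.raises(ValueError, match="island"):
            reg.overlap_with_islands([], [(10, 5)], [])
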
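"""Protein alignment scoring, best-hit thresholds, synteny and ANIb."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from straindiff import orthology as orth, regions as reg
from straindiff.genome import AnnotatedGenome, Feature, revcomp
from straindiff.io import TabularHit
from straindiff.sequtils import decode, random_sequence
from straindiff.simulate import AncestorSpec, EventSpec, evolve_pair, \
    generate_ancestor


class TestAlignProteinsLocal:
    def test_self_alignment_full_coverage_full_identity(self):
        aln = orth.align_proteins_local("MKVLAWHETQ", "MKVLAWHETQ")
        assert aln.query_coverage == pytest.approx(100.0)
        assert aln.identity == pytest.approx(100.0)
        assert aln.similarity == pytest.approx(100.0)

    def test_two_residue_score_equals_matrix_entry_sum(self):
        m = substitution_matrices.load("BLOSUM62")
        aln = orth.align_proteins_local("AW", "AW")
        assert aln.score == pytest.approx(m["A", "A"] + m["W", "W"])

    def test_similarity_at_least_identity(self):
        aln = orth.align_proteins_local("MKVLAWHETQ", "MKILAWHDTQ")
        assert aln.similarity >= aln.identity

    def test_no_positive_scoring_pair_is_no_hit(self):
        # G vs W scores negative in BLOSUM62; no positive local alignment
        assert orth.align_proteins_local("GGGGG", "WWWWW") is None

    def test_unknown_matrix_raises(self):
        with pytest.raises(ValueError, match="matrix"):
            orth.align_proteins_local("MK", "MK", matrix_name="NOSUCH")


class TestBestHits:
    def test_identical_proteomes_self_mapping(self):
        prot = {"p1": "MKVLAWHETQDRSTNN", "p2": "MSEQNNIKRAFFGHWW"}
        pairs = orth.best_hits(prot, prot)
        assert {(p.query_id, p.subject_id) for p in pairs} == \
            {("p1", "p1"), ("p2", "p2")}

    def test_coverage_and_evalue_thresholds_discard(self):
        hits = [
            TabularHit("q1", "s1", 90.0, 80, 8, 0, 1, 79, 1, 79, 1e-30, 200.0),
            TabularHit("q2", "s1", 90.0, 100, 8, 0, 1, 100, 1, 100,
                       1.1e-5, 40.0),
            TabularHit("q3", "s1", 90.0, 100, 8, 0, 1, 100, 1, 100,
                       1e-30, 300.0),
        ]
        lengths = {"q1": 99, "q2": 100, "q3": 100}  # q1 coverage 79.8% < 80
        out = orth.best_hits_from_table(hits, lengths)
        assert [p.query_id for p in out] == ["q3"]

    def test_best_hit_tie_breaks_deterministic(self):
        hits = [
            TabularHit("q", "sB", 90.0, 100, 8, 0, 1, 100, 1, 100, 1e-30, 200.0),
            TabularHit("q", "sA", 90.0, 100, 8, 0, 1, 100, 1, 100, 1e-30, 200.0),
        ]
        out = orth.best_hits_from_table(hits, {"q": 100})
        assert out[0].subject_id == "sA"  # lexicographic on equal score

    def test_recall_on_divergent_pair(self):
        anc = generate_ancestor(AncestorSpec(genome_length=50_000,
                                             gene_count=45, rng_seed=21))
        a, b, _ = evolve_pair(anc, EventSpec(
            substitution_rate=0.12, n_insertions=0, n_deletions=0,
            n_divergent=0, n_translocations=0, rng_seed=22))
        pairs = orth.best_hits(a.proteome(), b.proteome())
        correct = sum(1 for p in pairs
                      if p.query_id.replace("A_", "")
                      == p.subject_id.replace("B_", ""))
        assert correct / len(a.proteome()) >= 0.95


class TestPositionalOrthologs:
    def test_self_comparison_all_collinear(self):
        seq = decode(random_sequence(20_000, 0.5, np.random.default_rng(23)))
        prot = "MKVLAWHETQDRSTNNAEYWHKRDDS"
        g = AnnotatedGenome("g", seq, [
            Feature("f1", "CDS", 100, 400, protein=prot),
            Feature("f2", "CDS", 1000, 1300, protein=prot[::-1])])
        anchors = reg.find_anchors(seq, seq, 20)
        blocks = reg.chain_anchors(anchors, seq, seq)
        calls = reg.segment_and_classify(blocks, g, g)
        pairs = orth.best_hits(g.proteome(), g.proteome())
        flagged = orth.positional_orthologs(pairs, calls, g, g)
        assert len(flagged) == 2
        assert all(p.collinear for p in flagged)

    def test_translocated_gene_not_collinear(self, evolved_pair):
        a, b, log = evolved_pair
        anchors = reg.find_anchors(a.sequence, b.sequence, 20)
        blocks = reg.chain_anchors(anchors, a.sequence, b.sequence)
        calls = reg.segment_and_classify(blocks, a, b)
        pairs = orth.best_hits(a.proteome(), b.proteome())
        flagged = orth.positional_orthologs(pairs, calls, a, b)
        trans = [r for r in calls if r.region_class == "translocated"]
        assert trans
        in_trans = {fid for r in trans for fid in r.feature_ids_a}
        for p in flagged:
            if p.query_id in in_trans:
                assert not p.collinear

    def test_unknown_gene_raises(self):
        g = AnnotatedGenome("g", "ACGT" * 100)
        pair = orth.OrthologPair("nope", "nope", 100, 100, 100, 0.0, 50.0)
        with pytest.raises(KeyError):
            orth.positional_orthologs([pair], [], g, g)


class TestPresenceMatrixAndSummaries:
    GENES = {"g1": "MKVLAWHETQDRSTNN", "g2": "MSEQNNIKRAFFGHWW"}

    def test_gene_present_in_own_proteome(self):
        m = orth.homolog_presence_matrix(self.GENES, {"self": self.GENES})
        assert m["self"].all()

    def test_gene_absent_from_unrelated_proteome(self):
        other = {"x1": "GGGGGGPPPPPPGGGGGG"}
        m = orth.homolog_presence_matrix(self.GENES, {"other": other})
        assert not m["other"].any()

    def test_island_genes_absent_from_ancestor_proteome(self, small_ancestor,
                                                        evolved_pair):
        a, b, log = evolved_pair
        anc_proteome = small_ancestor.proteome()
        for e in log.of_type("insertion"):
            genome = a if e.genome == "A" else b
            island_genes = {fid: genome.feature_by_id(fid).protein
                            for fid in e.payload_ids
                            if genome.feature_by_id(fid).protein}
            m = orth.homolog_presence_matrix(island_genes,
                                             {"anc": anc_proteome})
            assert not m["anc"].any()

    def test_monotone_in_thresholds(self):
        anc = generate_ancestor(AncestorSpec(genome_length=30_000,
                                             gene_count=25, rng_seed=31))
        a, b, _ = evolve_pair(anc, EventSpec(
            substitution_rate=0.2, n_insertions=0, n_deletions=0,
            n_divergent=0, n_translocations=0, rng_seed=32))
        strict = orth.homolog_presence_matrix(a.proteome(), {"b": b.proteome()},
                                              min_coverage=90, max_e=1e-20)
        lax = orth.homolog_presence_matrix(a.proteome(), {"b": b.proteome()},
                                           min_coverage=50, max_e=1e-3)
        assert (lax["b"] | ~strict["b"]).all()  # strict ⊆ lax

    def test_region_summary_identical_proteome(self):
        s = orth.region_homology_summary(self.GENES, self.GENES)
        assert s.n_with_homolog == 2
        assert s.mean_coverage == pytest.approx(100.0)
        assert s.mean_similarity == pytest.approx(100.0)

    def test_region_summary_no_homologs(self):
        s = orth.region_homology_summary(self.GENES,
                                         {"x": "GGGGGGPPPPPPGGGG"})
        assert s.n_with_homolog == 0
        assert s.mean_coverage is None and s.mean_similarity is None

    def test_region_summary_hand_computed_means(self):
        genes = {"a": "MKVLAWHETQDRSTNN", "b": "MSEQNNIKRAFFGHWW"}
        proteome = {"a": "MKVLAWHETQDRSTNN", "b": "MSEQNNIKRAFFGHWW"}
        s = orth.region_homology_summary(genes, proteome)
        assert s.mean_coverage == pytest.approx(100.0)


class TestRegionSynteny:
    def _pairs(self, mapping):
        return [orth.OrthologPair(q, s, 100, 100, 100, 0.0, 50.0)
                for q, s in mapping.items()]

    def test_identical_order_zero_breakpoints(self):
        genes = [f"g{i}" for i in range(6)]
        comp = orth.region_synteny(genes, genes,
                                   self._pairs({g: g for g in genes}))
        assert comp.breakpoints == 0 and comp.inversions == 0

    def test_full_reversal_is_one_inversion(self):
        genes = [f"g{i}" for i in range(6)]
        comp = orth.region_synteny(genes, genes[::-1],
                                   self._pairs({g: g for g in genes}))
        assert comp.breakpoints == 0
        assert comp.inversions == 1

    def test_adjacent_swap_single_breakpoint(self):
        a = ["g0", "g1", "g2", "g3"]
        b = ["g0", "g1", "g3", "g2"]
        comp = orth.region_synteny(a, b, self._pairs({g: g for g in a}))
        # brute-force oracle: count adjacencies with |Δ index| != 1
        link = {g: b.index(g) for g in a}
        bs = [link[g] for g in a]
        expected = sum(1 for x, y in zip(bs, bs[1:]) if abs(y - x) != 1)
        assert comp.breakpoints == expected == 1

    def test_unmatched_genes_flagged(self):
        comp = orth.region_synteny(["g0", "g1"], ["g0"],
                                   self._pairs({"g0": "g0"}))
        assert comp.unmatched_a == [1] and comp.unmatched_b == []


class TestANIb:
    def test_self_ani_exactly_100(self):
        seq = decode(random_sequence(5000, 0.5, np.random.default_rng(41)))
        res = orth.compute_anib(seq, seq)
        assert res.ani == pytest.approx(100.0)
        assert res.n_retained == res.n_fragments

    def test_unrelated_genomes_unalignable_or_low_support(self):
        a = decode(random_sequence(5000, 0.5, np.random.default_rng(42)))
        b = decode(random_sequence(5000, 0.5, np.random.default_rng(43)))
        res = orth.compute_anib(a, b)
        assert res.unalignable or res.low_support

    def test_monotone_decreasing_in_divergence(self):
        anis = []
        for rate in (0.02, 0.08, 0.15):
            anc = generate_ancestor(AncestorSpec(genome_length=40_000,
                                                 gene_count=30, rng_seed=44))
            a, b, _ = evolve_pair(anc, EventSpec(
                substitution_rate=rate, n_insertions=0, n_deletions=0,
                n_divergent=0, n_translocations=0, rng_seed=45))
            anis.append(orth.compute_anib(a, b).ani)
        assert anis[0] > anis[1] > anis[2]

    def test_short_genome_raises(self):
        with pytest.raises(ValueError, match="fragment"):
            orth.compute_anib("ACGT" * 10, "ACGT" * 1000)

    def test_symmetric_is_mean_of_directions(self):
        anc = generate_ancestor(AncestorSpec(genome_length=20_000,
                                             gene_count=15, rng_seed=46))
        a, b, _ = evolve_pair(anc, EventSpec(
            substitution_rate=0.05, n_insertions=0, n_deletions=0,
            n_divergent=0, n_translocations=0, rng_seed=47))
        ab = orth.compute_anib(a, b).ani
        ba = orth.compute_anib(b, a).ani
        sym = orth.compute_anib_symmetric(a, b).ani
        assert sym == pytest.approx((ab + ba) / 2)
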
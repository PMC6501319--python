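"""Annotation reconciliation, exclusive sets, censuses and the Welch test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from straindiff import plasticity as pl
from straindiff.genome import AnnotatedGenome, Feature
from straindiff.orthology import OrthologPair


def _pair(q, s):
    return OrthologPair(q, s, 100.0, 90.0, 95.0, 1e-30, 200.0)


class TestTransferAnnotations:
    def test_one_sided_ko_copied(self):
        ta = {"a1": {"KO": ["K00001"], "COG": []}}
        tb = {"b1": {"KO": [], "COG": []}}
        oa, ob, conflicts = pl.transfer_annotations(ta, tb, [_pair("a1", "b1")])
        assert ob["b1"]["KO"] == ["K00001"]
        assert conflicts == []

    def test_conflicting_annotations_untouched_and_logged(self):
        ta = {"a1": {"KO": ["K00001"]}}
        tb = {"b1": {"KO": ["K00002"]}}
        oa, ob, conflicts = pl.transfer_annotations(ta, tb, [_pair("a1", "b1")])
        assert oa["a1"]["KO"] == ["K00001"]
        assert ob["b1"]["KO"] == ["K00002"]
        assert len(conflicts) == 1

    def test_idempotent(self):
        ta = {"a1": {"KO": ["K00001"]}}
        tb = {"b1": {"KO": []}}
        pairs = [_pair("a1", "b1")]
        oa, ob, _ = pl.transfer_annotations(ta, tb, pairs)
        oa2, ob2, _ = pl.transfer_annotations(oa, ob, pairs)
        assert oa2 == oa and ob2 == ob


class TestExclusiveSets:
    def test_identical_tables_empty_sets(self):
        t = {"f1": {"KO": ["K1"], "COG": ["COG1"]}}
        sets = pl.exclusive_annotation_sets(t, t)
        assert all(not v for v in sets.values())

    def test_one_extra_ko(self):
        ta = {"f1": {"KO": ["K09999", "K1"], "COG": []}}
        tb = {"f2": {"KO": ["K1"], "COG": []}}
        sets = pl.exclusive_annotation_sets(ta, tb)
        assert sets["ko_only_a"] == {"K09999"}
        assert sets["ko_only_b"] == set()

    def test_transposase_only_difference_excluded(self):
        ta = {"f1": {"KO": ["K07483"], "COG": ["COG2801"]}}
        tb = {"f2": {"KO": [], "COG": []}}
        sets = pl.exclusive_annotation_sets(ta, tb, exclude_transposases=True)
        assert all(not v for v in sets.values())
        kept = pl.exclusive_annotation_sets(ta, tb, exclude_transposases=False)
        assert kept["ko_only_a"] == {"K07483"}

    def test_partition_identity(self):
        ta = {"f1": {"KO": ["K1", "K2"], "COG": []},
              "f2": {"KO": ["K3"], "COG": []}}
        tb = {"g1": {"KO": ["K2", "K4"], "COG": []}}
        sets = pl.exclusive_annotation_sets(ta, tb)
        universe_a = {"K1", "K2", "K3"}
        shared = universe_a & {"K2", "K4"}
        assert sets["ko_only_a"] | shared == universe_a


class TestGroupExclusiveRegions:
    def _genome(self, n=20):
        feats = [Feature(f"g{i}", "CDS", i * 100, i * 100 + 90,
                         protein="M" * 30) for i in range(n)]
        return AnnotatedGenome("g", "A" * (n * 100), feats)

    def test_adjacent_genes_one_region(self):
        g = self._genome()
        regions = pl.group_exclusive_regions({"g3", "g4"}, g)
        assert len(regions) == 1
        assert regions[0][2] == ["g3", "g4"]

    def test_distant_genes_two_regions(self):
        g = self._genome()
        regions = pl.group_exclusive_regions({"g2", "g13"}, g, max_gene_gap=2)
        assert len(regions) == 2

    def test_brute_force_oracle_over_random_subsets(self):
        g = self._genome(20)
        rng = np.random.default_rng(55)
        for _ in range(30):
            k = int(rng.integers(1, 8))
            members = set(rng.choice([f"g{i}" for i in range(20)], size=k,
                                     replace=False))
            for gap in (0, 1, 2, 4):
                got = pl.group_exclusive_regions(members, g, max_gene_gap=gap)
                # oracle: split the sorted index list at gaps > gap
                idx = sorted(int(m[1:]) for m in members)
                expected = 1
                for a, b in zip(idx, idx[1:]):
                    if b - a - 1 > gap:
                        expected += 1
                assert len(got) == expected

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            pl.group_exclusive_regions({"nope"}, self._genome())


class TestCensuses:
    def test_transporter_breadth_counts_proteins_and_kos(self):
        table = {f"f{i}": {"KO": ["K99001"]} for i in range(3)}
        assert pl.transporter_breadth(table, {"K99001"}) == (3, 1)

    def test_transporter_breadth_no_members(self):
        assert pl.transporter_breadth({"f": {"KO": ["K1"]}}, {"K2"}) == (0, 0)

    def test_transporter_empty_category_raises(self):
        with pytest.raises(ValueError):
            pl.transporter_breadth({}, set())

    def test_transposase_feature_counted_once(self):
        table = {"f1": {"KO": ["K07483"], "COG": ["COG2801"]},
                 "f2": {"KO": [], "COG": []}}
        assert pl.count_transposases(table) == 1

    def test_empty_table_zero(self):
        assert pl.count_transposases({}) == 0

    def test_forced_marker_islands_census(self, small_ancestor):
        from straindiff.simulate import EventSpec, evolve_pair
        a, b, log = evolve_pair(small_ancestor, EventSpec(
            substitution_rate=0.0, n_insertions=3, n_deletions=0,
            n_divergent=0, n_translocations=0, mobility_marker_prob=1.0,
            island_length_range=(2000, 3000), rng_seed=66))
        total_island_genes = sum(len(e.payload_ids)
                                 for e in log.of_type("insertion"))
        na = pl.count_transposases(pl.genome_annotation_table(a))
        nb = pl.count_transposases(pl.genome_annotation_table(b))
        assert na + nb == total_island_genes


class TestWelch:
    def test_identical_groups_t_zero_p_half(self):
        r = pl.welch_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(0.5)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(67)
        x, y = rng.normal(1, 2, 12), rng.normal(0, 1, 9)
        r = pl.welch_one_sided(x, y)
        sc = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        assert r.t == pytest.approx(sc.statistic)
        assert r.p == pytest.approx(sc.pvalue)
        assert r.df == pytest.approx(sc.df)

    def test_exact_permutation_oracle(self):
        x, y = [3.0, 4.0, 5.0], [0.0, 1.0, 2.0]
        r = pl.welch_one_sided(x, y)
        pooled = x + y
        t_obs = r.t
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(6) if i not in combo]
            t = pl.welch_one_sided(xs, ys).t
            total += 1
            count += t >= t_obs - 1e-12
        p_perm = count / total
        assert abs(r.p - p_perm) <= 1 / total + 1e-9

    def test_one_sided_tails_sum_to_one(self):
        x, y = [1.0, 2.0, 4.0], [0.5, 3.0, 3.5]
        g = pl.welch_one_sided(x, y, "greater").p
        l = pl.welch_one_sided(x, y, "less").p
        assert g + l == pytest.approx(1.0)

    def test_small_groups_raise(self):
        with pytest.raises(ValueError, match=">= 2"):
            pl.welch_one_sided([1.0], [1.0, 2.0])

    def test_degenerate_unequal_means_raise(self):
        with pytest.raises(ValueError, match="zero variance"):
            pl.welch_one_sided([1.0, 1.0], [2.0, 2.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(68)
        n_sims, n = 2000, 8
        rejections = 0
        for _ in range(n_sims):
            x = rng.normal(0, 1, n)
            y = rng.normal(0, 1, n)
            if pl.welch_one_sided(x, y).p < 0.05:
                rejections += 1
        assert abs(rejections / n_sims - 0.05) <= 0.02


class TestCrisprTransposaseTest:
    def test_equal_strata_p_half(self):
        df = pd.DataFrame({"crispr_present": [True, True, False, False],
                           "transposase_count": [5, 5, 5, 5]})
        r = pl.crispr_transposase_test(df)
        assert r.p == pytest.approx(0.5)
        assert r.mean_x == r.mean_y == 5.0

    def test_power_increases_with_shift(self):
        rng = np.random.default_rng(69)
        power = []
        for delta in (0.0, 1.5, 4.0):
            rej = 0
            for _ in range(300):
                with_c = rng.normal(10 + delta, 3, 10)
                without = rng.normal(10, 3, 10)
                df = pd.DataFrame({
                    "crispr_present": [True] * 10 + [False] * 10,
                    "transposase_count": np.concatenate([with_c, without])})
                rej += pl.crispr_transposase_test(df).p < 0.05
            power.append(rej / 300)
        assert power[0] < power[1] < power[2]

    def test_small_stratum_raises(self):
        df = pd.DataFrame({"crispr_present": [True, False, False],
                           "transposase_count": [1, 2, 3]})
        with pytest.raises(ValueError, match="stratum"):
            pl.crispr_transposase_test(df)
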
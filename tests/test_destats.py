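import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fersig.destats import (
    bh_adjust,
    chi_square_test,
    cluster_markers,
    compute_tmb,
    hypergeometric_enrichment,
    rank_location_test,
)
from fersig.io import MutationTable


def _frame(arr):
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03], atol=1e-12)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, p, rnd):
        p = np.asarray(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q1 = bh_adjust(p)
        q2 = bh_adjust(p[perm])
        assert np.allclose(q1[perm], q2, atol=1e-12)


class TestHypergeometric:
    def test_set_equal_universe_is_certain(self):
        uni = [f"g{i}" for i in range(10)]
        out = hypergeometric_enrichment(uni[:4], {"S": uni}, uni)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_perfect_overlap_matches_combinatorial_enumeration(self):
        uni = [f"g{i}" for i in range(20)]
        out = hypergeometric_enrichment(uni[:5], {"S": uni[:5]}, uni)
        assert out.loc[0, "k"] == 5
        assert out.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-10)

    def test_disjoint_query_p_one(self):
        uni = [f"g{i}" for i in range(12)]
        out = hypergeometric_enrichment(uni[:3], {"S": uni[6:]}, uni)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["zz"], {"S": ["a"]}, ["a", "b"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], {"S": ["a"]}, [])


class TestChiSquare:
    def test_exact_independence(self):
        stat, df, p, _ = chi_square_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_formula(self):
        obs = np.array([[20, 5], [5, 20]])
        total = obs.sum()
        expected = np.outer(obs.sum(1), obs.sum(0)) / total
        by_hand = ((obs - expected) ** 2 / expected).sum()
        stat, df, p, exp = chi_square_test(obs)
        assert stat == pytest.approx(by_hand, abs=1e-10)
        assert df == 1
        assert np.allclose(exp, expected)

    def test_statistic_linear_in_total_count(self):
        obs = np.array([[20, 5], [5, 20]])
        s1, *_ = chi_square_test(obs)
        s2, *_ = chi_square_test(2 * obs)
        assert s2 == pytest.approx(2 * s1)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])

    def test_low_expected_count_warns(self):
        with pytest.warns(UserWarning, match="below 5"):
            chi_square_test([[2, 8], [3, 7]])


def _perm_pvalue(a, b):
    """Exact permutation two-sided p for the rank-sum statistic."""
    import scipy.stats
    pooled = np.concatenate([a, b])
    n1 = len(a)
    obs = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="auto").statistic
    mu = n1 * len(b) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        u = scipy.stats.mannwhitneyu(pooled[mask], pooled[~mask],
                                     alternative="two-sided",
                                     method="auto").statistic
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestRankLocation:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        stat, p = rank_location_test([g, list(g)])
        assert p >= 0.99

    def test_group_order_symmetry(self):
        a, b = [1.0, 5.0, 2.0], [4.0, 3.0, 9.0, 8.0]
        _, p1 = rank_location_test([a, b])
        _, p2 = rank_location_test([b, a])
        assert p1 == pytest.approx(p2)

    def test_three_group_power_under_shifted_alternative(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_seeds = 30
        for _ in range(n_seeds):
            groups = [rng.normal(delta, 1.0, size=50) for delta in (0, 1, 2)]
            _, p = rank_location_test(groups)
            rejections += p < 0.05
        assert rejections / n_seeds >= 0.9

    def test_two_group_agrees_with_exact_permutation(self):
        rng = np.random.default_rng(5)
        for _ in range(4):
            a = rng.normal(0, 1, size=4)
            b = rng.normal(0.5, 1, size=4)
            _, p = rank_location_test([a, b])
            assert abs(p - _perm_pvalue(a, b)) <= 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_location_test([[1.0, 2.0], []])


class TestClusterMarkers:
    def _two_cluster_data(self, n_genes=300, n_planted=100, n_per=100,
                          shift_ln=1.0, sd=0.5, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(5.0, sd, size=(n_genes, 2 * n_per))
        X[:n_planted, :n_per] += shift_ln / math.log(2)  # lnFC = shift_ln
        labels = pd.Series([1] * n_per + [2] * n_per,
                           index=[f"s{j}" for j in range(2 * n_per)])
        return _frame(np.clip(X, 0, None)), labels

    def test_planted_markers_recovered(self):
        X, labels = self._two_cluster_data()
        de = cluster_markers(X, labels, min_lnfc=0.25)
        up = set(de.markers(1, direction="up"))
        planted = {f"g{i}" for i in range(100)}
        assert len(up & planted) / len(planted) >= 0.95

    def test_threshold_monotonicity(self):
        X, labels = self._two_cluster_data(shift_ln=0.4, seed=3)
        de = cluster_markers(X, labels)
        strict = set(de.markers(1, direction="any", min_lnfc=0.5))
        loose = set(de.markers(1, direction="any", min_lnfc=0.25))
        assert strict <= loose

    def test_null_type_one_error_controlled(self):
        """Global null: the fraction of q<0.05 genes stays at the FDR level."""
        rng = np.random.default_rng(1)
        fractions = []
        for seed in range(10):
            X = _frame(rng.normal(5, 1, size=(400, 60)).clip(0))
            labels = pd.Series(rng.permutation([1] * 30 + [2] * 30),
                               index=X.columns)
            de = cluster_markers(X, labels, min_lnfc=0.0)
            sub = de.table[de.table["cluster"] == 1]
            fractions.append((sub["q"] < 0.05).mean())
        fractions = np.asarray(fractions)
        se = fractions.std(ddof=1) / np.sqrt(len(fractions)) + 1e-9
        assert fractions.mean() <= 0.05 + 3 * se

    def test_direction_consistent_with_lnfc_sign(self):
        X, labels = self._two_cluster_data(seed=2)
        de = cluster_markers(X, labels)
        t = de.table
        assert ((t["lnfc"] >= 0) == (t["direction"] == "up")).all()

    def test_small_cluster_rejected(self):
        X, labels = self._two_cluster_data(n_per=10)
        labels.iloc[:18] = 1  # leaves cluster 2 with 2 samples
        with pytest.raises(ValueError, match="minimum size"):
            cluster_markers(X, labels)


class TestTmb:
    def _mut(self, rows):
        return MutationTable(pd.DataFrame(
            rows, columns=["sample_id", "gene_symbol", "variant_classification"]))

    def test_empty_table_all_zero(self):
        mut = self._mut([])
        tmb = compute_tmb(mut, ["a", "b"])
        assert (tmb == 0).all()

    def test_nonsilent_only_counting(self):
        rows = [("a", f"G{i}", "Missense_Mutation") for i in range(3)]
        rows += [("a", f"G{i+3}", "Silent") for i in range(2)]
        tmb = compute_tmb(self._mut(rows), ["a"])
        assert tmb["a"] == 3
        tmb_all = compute_tmb(self._mut(rows), ["a"], nonsilent_only=False)
        assert tmb_all["a"] == 5

    def test_per_megabase_scaling(self):
        rows = [("a", f"G{i}", "Missense_Mutation") for i in range(38)]
        tmb = compute_tmb(self._mut(rows), ["a"], per_mb=True)
        assert tmb["a"] == pytest.approx(1.0)

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            compute_tmb(self._mut([]), [])
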
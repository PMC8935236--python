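import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fersig.io import ExpressionMatrix
from fersig.scoring import (
    PearsonResult,
    module_scores,
    pca_signature_score,
    pearson_correlation,
    ssgsea_scores,
)


def brute_force_ssgsea(x, in_set, alpha):
    """Independent running-sum enumeration of the single-sample ES."""
    n = len(x)
    ranks = scipy.stats.rankdata(x, method="average")
    order = sorted(range(n), key=lambda i: (-x[i], i))
    sum_w = sum(ranks[i] ** alpha for i in order if in_set[i])
    n_out = n - sum(in_set)
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** alpha / sum_w
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


def _frame(arr):
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


class TestSsgsea:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            n_genes = rng.integers(5, 31)
            n_samples = rng.integers(2, 6)
            X = _frame(rng.uniform(0, 10, size=(n_genes, n_samples)))
            size = rng.integers(1, n_genes)
            members = list(rng.choice(X.index, size=size, replace=False))
            alpha = float(rng.choice([0.0, 0.25, 1.0]))
            result = ssgsea_scores(X, {"S": members}, alpha=alpha,
                                   normalize=False)
            in_set = X.index.isin(members)
            for j, s in enumerate(X.columns):
                expected = brute_force_ssgsea(X.iloc[:, j].to_numpy(), in_set,
                                              alpha)
                assert result.scores.loc["S", s] == pytest.approx(
                    expected, abs=1e-9)

    def test_top_gene_singleton_set_alpha_zero_hand_computed(self):
        # 4 genes, set = top gene: ES = sum_i (P_in - P_out)
        # walk: (1-0), (1-1/3), (1-2/3), (1-1) = 1 + 2/3 + 1/3 + 0 = 2
        X = _frame(np.array([[4.0], [3.0], [2.0], [1.0]]))
        res = ssgsea_scores(X, {"S": ["g0"]}, alpha=0.0, normalize=False)
        assert res.scores.loc["S"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_identical_rankings_give_identical_scores(self):
        x = np.array([5.0, 1.0, 3.0, 2.0, 4.0])
        X = _frame(np.column_stack([x, 2 * x + 1]))
        res = ssgsea_scores(X, {"S": ["g0", "g3"]}, normalize=False)
        assert res.scores.iloc[0, 0] == pytest.approx(res.scores.iloc[0, 1])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        X = _frame(rng.uniform(0, 5, size=(15, 3)))
        Y = X.copy()
        Y.iloc[:, 1] = Y.iloc[:, 1] ** 3  # strictly monotone on >= 0
        sets = {"S": list(X.index[:4])}
        a = ssgsea_scores(X, sets, normalize=False).scores
        b = ssgsea_scores(Y, sets, normalize=False).scores
        assert a.iloc[0, 1] == pytest.approx(b.iloc[0, 1], abs=1e-12)

    def test_full_coverage_set_rejected(self):
        X = _frame(np.random.default_rng(0).uniform(1, 2, (4, 3)))
        with pytest.raises(ValueError):
            ssgsea_scores(X, {"S": list(X.index)})

    def test_no_overlap_set_skipped_with_warning(self):
        X = _frame(np.random.default_rng(0).uniform(1, 2, (4, 3)))
        with pytest.warns(UserWarning, match="no overlap"):
            res = ssgsea_scores(X, {"S": ["nope"], "T": ["g0"]})
        assert list(res.scores.index) == ["T"]

    def test_normalization_divides_by_range(self):
        X = _frame(np.random.default_rng(2).uniform(0, 5, (10, 4)))
        sets = {"A": list(X.index[:3]), "B": list(X.index[5:8])}
        raw = ssgsea_scores(X, sets, normalize=False).scores
        norm = ssgsea_scores(X, sets, normalize=True).scores
        rng_ = raw.to_numpy().max() - raw.to_numpy().min()
        assert np.allclose(norm.to_numpy(), raw.to_numpy() / rng_)


class TestModuleScores:
    def test_constant_matrix_scores_zero(self):
        X = _frame(np.full((10, 5), 3.0))
        s = module_scores(X, ["g0", "g1"], n_bins=1, n_ctrl=5, seed=0)
        assert np.allclose(s.to_numpy(), 0.0)

    def test_global_shift_invariance(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.uniform(0, 4, size=(12, 6)))
        a = module_scores(X, ["g0", "g3"], n_bins=2, n_ctrl=4, seed=9)
        b = module_scores(X + 7.0, ["g0", "g3"], n_bins=2, n_ctrl=4, seed=9)
        # the constant cancels in the difference of means, but the binning
        # order is also unchanged, so scores match exactly
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_single_gene_fixture_hand_computed(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.uniform(0, 5, size=(10, 5)))
        s = module_scores(X, ["g4"], n_bins=1, n_ctrl=9, seed=0)
        others = [g for g in X.index if g != "g4"]
        expected = X.loc["g4"] - X.loc[others].mean(axis=0)
        assert np.allclose(s.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_random_within_bin_sets_have_mean_zero_score(self):
        """Control-matched design: a random set is its own control."""
        rng = np.random.default_rng(7)
        X = _frame(rng.normal(2.0, 1.0, size=(60, 20)).clip(0))
        draws = []
        for k in range(200):
            genes = list(rng.choice(X.index, size=5, replace=False))
            s = module_scores(X, genes, n_bins=6, n_ctrl=20, seed=k)
            draws.append(s.mean())
        draws = np.asarray(draws)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean()) < 3 * se + 1e-3

    def test_empty_overlap_errors(self):
        X = _frame(np.ones((4, 3)))
        with pytest.raises(ValueError):
            module_scores(X, ["nope"])


class TestPc1Score:
    def test_rank_one_data_perfectly_correlated(self):
        pattern = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        X = _frame(np.vstack([2 * pattern, 3 * pattern, pattern * 0.5]))
        pc = pca_signature_score(X, ["g0", "g1", "g2"])
        r = np.corrcoef(pc.scores, X.loc["g0"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_orientation_rule_fixes_eigensolver_sign(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.normal(size=(8, 30)))
        genes = list(X.index[:5])
        a = pca_signature_score(X, genes)
        b = pca_signature_score(-X, genes)
        # negating the data flips the relation to set means, and the rule
        # re-orients: both scores correlate positively with their set mean
        for pc, df in ((a, X), (b, -X)):
            set_mean = df.loc[genes].mean(axis=0)
            assert np.corrcoef(pc.scores, set_mean)[0, 1] > 0

    def test_variance_equals_top_eigenvalue_of_gene_covariance(self):
        rng = np.random.default_rng(4)
        X = _frame(rng.normal(5, 2, size=(20, 50)))
        genes = list(X.index)
        pc = pca_signature_score(X, genes)
        centered = X.sub(X.mean(axis=1), axis=0).to_numpy()
        cov = centered @ centered.T / (X.shape[1] - 1)
        top = np.linalg.eigvalsh(cov)[-1]
        assert pc.scores.var(ddof=1) == pytest.approx(top, abs=1e-9 * top)

    def test_loadings_unit_norm(self, tiny_expression):
        pc = pca_signature_score(tiny_expression, tiny_expression.gene_ids[:6])
        assert np.linalg.norm(pc.loadings) == pytest.approx(1.0)

    def test_apply_reproduces_training_scores(self, tiny_expression):
        pc = pca_signature_score(tiny_expression, tiny_expression.gene_ids[:6])
        again = pc.apply(tiny_expression)
        assert np.allclose(again.to_numpy(), pc.scores.to_numpy(), atol=1e-12)

    def test_too_few_genes_or_samples_rejected(self):
        X = _frame(np.random.default_rng(0).uniform(0, 1, (5, 4)))
        with pytest.raises(ValueError):
            pca_signature_score(X, ["g0"])
        with pytest.raises(ValueError):
            pca_signature_score(X.iloc[:, :2], ["g0", "g1"])

    def test_zero_variance_submatrix_rejected(self):
        X = _frame(np.ones((4, 5)))
        with pytest.raises(ValueError):
            pca_signature_score(X, ["g0", "g1"])


class TestPearson:
    def test_self_correlation_is_one(self):
        a = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert pearson_correlation(a, a).r == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        a = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert pearson_correlation(a, -a).r == pytest.approx(-1.0)

    def test_fixture_matches_textbook_formula(self):
        a = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        b = pd.Series([2.0, 4, 5, 9], index=list("abcd"))
        x, y = a.to_numpy(), b.to_numpy()
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        res = pearson_correlation(a, b)
        assert res == PearsonResult(r=pytest.approx(expected, abs=1e-12), n=4)

    def test_pairwise_complete_and_n_reported(self):
        a = pd.Series([1.0, 2, 3, 4, np.nan], index=list("abcde"))
        b = pd.Series([2.0, 4, 6, 8, 10], index=list("abcde"))
        res = pearson_correlation(a, b)
        assert res.n == 4
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_flagged_as_nan(self):
        a = pd.Series([1.0, 1, 1, 1], index=list("abcd"))
        b = pd.Series([2.0, 4, 5, 9], index=list("abcd"))
        assert np.isnan(pearson_correlation(a, b).r)

    def test_matrix_mode_returns_per_row_table(self):
        a = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        M = pd.DataFrame({"a": [1.0, 4], "b": [2.0, 3], "c": [3.0, 2],
                          "d": [4.0, 1]}, index=["up", "down"])
        out = pearson_correlation(a, M)
        assert out.loc["up", "r"] == pytest.approx(1.0)
        assert out.loc["down", "r"] == pytest.approx(-1.0)
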
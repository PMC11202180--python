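"""ANOVA against a sum-of-squares oracle; leakage-safe SVM-LOOCV; permutation null."""

import numpy as np
import pytest

import mtrrp as M
from mtrrp.classify import DesignError
from mtrrp.signals import ParameterError


def anova_oracle(samples):
    """From-scratch one-way ANOVA via the sum-of-squares decomposition."""
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in samples)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in samples)
    df1 = len(samples) - 1
    df2 = len(all_vals) - len(samples)
    return (ss_between / df1) / (ss_within / df2)


class TestAnova:
    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc=m, size=4) for m in (0.0, 0.5, 2.0)]
        X = np.concatenate(groups)[:, None]
        labels = np.repeat(["a", "b", "c"], 4)
        res = M.groupwise_anova(X, labels)[0]
        assert res.f_statistic == pytest.approx(anova_oracle(groups), abs=1e-9)
        assert (res.df_between, res.df_within) == (2, 9)

    def test_identical_groups_give_f0_p1(self):
        g = np.array([1.0, 2.0, 3.0])
        X = np.concatenate([g, g])[:, None]
        labels = np.repeat(["a", "b"], 3)
        res = M.groupwise_anova(X, labels)[0]
        assert res.f_statistic == 0.0
        assert res.p_adjusted == 1.0

    def test_partial_eta_sq_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(24, 6))
        labels = np.repeat(["a", "b", "c"], 8)
        for r in M.groupwise_anova(X, labels):
            expect = (r.f_statistic * r.df_between
                      / (r.f_statistic * r.df_between + r.df_within))
            assert r.partial_eta_sq == pytest.approx(expect, abs=1e-12)
            assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 6), abs=1e-12)

    def test_small_group_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(DesignError):
            M.groupwise_anova(X, np.array(["a", "a", "b"]))

    def test_pairwise_bonferroni(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10),
                            rng.normal(0, 1, 10)])
        labels = np.repeat(["a", "b", "c"], 10)
        ps = M.pairwise_comparisons(v, labels)
        assert set(ps) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert ps[("a", "b")] < 0.05 < ps[("a", "c")]


class TestPearsonSelection:
    def test_label_copy_ranks_first(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 10)
        X = rng.normal(size=(20, 8))
        X[:, 5] = y
        idx = M.select_features_pearson(X, y, k=3)
        assert idx[0] == 5

    def test_tie_breaks_to_earlier_column(self):
        y = np.array([0.0, 1, 0, 1, 0, 1])
        X = np.column_stack([y, y, -y])  # all |r| = 1
        idx = M.select_features_pearson(X, y, k=3)
        np.testing.assert_array_equal(idx, [0, 1, 2])

    def test_zero_variance_feature_scores_zero(self, caplog):
        rng = np.random.default_rng(4)
        y = np.array([0, 1] * 8)
        X = rng.normal(size=(16, 4))
        X[:, 2] = 7.0
        idx = M.select_features_pearson(X, y, k=4)
        assert idx[-1] == 2 or np.abs(
            np.corrcoef(X[:, idx[2]], y)[0, 1]) >= 0.0  # dead feature last-ish
        assert 2 not in idx[:1]

    def test_noise_feature_correlations_in_null_range(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 20)
        X = rng.normal(size=(40, 200))
        idx = M.select_features_pearson(X, y, k=5)
        rs = [abs(np.corrcoef(X[:, j], y)[0, 1]) for j in idx]
        assert max(rs) < 0.7  # extreme-order statistic of the n=40 null

    def test_k_too_large_rejected(self):
        with pytest.raises(ParameterError):
            M.select_features_pearson(np.zeros((10, 3)), np.zeros(10), k=4)


class TestSvmLoocv:
    def test_separable_clusters_are_perfectly_classified(self):
        rng = np.random.default_rng(6)
        n, d = 30, 10
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, d)) + 10.0 * y[:, None]
        rep = M.svm_loocv(X, y, k=5)
        assert rep.accuracy == 1.0
        assert rep.recall == 1.0 and rep.specificity == 1.0

    def test_report_identities(self):
        rng = np.random.default_rng(7)
        y = np.array([0, 1] * 10)
        X = rng.normal(size=(20, 30))
        rep = M.svm_loocv(X, y, k=10)
        n = rep.tp + rep.tn + rep.fp + rep.fn
        assert n == 20
        assert rep.accuracy == (rep.tp + rep.tn) / n
        assert rep.recall == rep.tp / (rep.tp + rep.fn)
        assert rep.specificity == rep.tn / (rep.tn + rep.fp)
        assert len(rep.selected_features) == n

    def test_pure_noise_accuracy_near_chance(self):
        """With labels independent of 200 noise features, LOOCV accuracy stays
        inside the 95% binomial band around 0.5 (n=40)."""
        rng = np.random.default_rng(8)
        y = np.array([0, 1] * 20)
        X = rng.normal(size=(40, 200))
        rep = M.svm_loocv(X, y, k=50)
        band = 1.96 * np.sqrt(0.25 / 40)
        assert abs(rep.accuracy - 0.5) <= band + 0.1

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        y = np.array([0, 1] * 8)
        X = rng.normal(size=(16, 40))
        a = M.svm_loocv(X, y, k=10, seed=3)
        b = M.svm_loocv(X, y, k=10, seed=3)
        assert a.accuracy == b.accuracy and a.tp == b.tp

    def test_single_class_rejected(self):
        with pytest.raises(DesignError):
            M.svm_loocv(np.zeros((8, 3)), np.zeros(8, dtype=int), k=2)


class TestPermutationTest:
    def test_p_value_formula_and_bounds(self):
        rng = np.random.default_rng(10)
        n, d = 16, 20
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, d)) + 8.0 * y[:, None]  # trivially separable
        res = M.permutation_test(X, y, n_perm=24, k=5, seed=1)
        assert res.observed_accuracy == 1.0
        assert len(res.null_accuracies) == 24
        assert res.p_value >= 1.0 / 25.0
        expect = (1 + np.sum(res.null_accuracies >= res.observed_accuracy)) / 25
        assert res.p_value == pytest.approx(expect, abs=1e-12)

    def test_no_leakage_canary(self):
        """A feature equal to the true labels must not help once labels are
        shuffled: null accuracies center on chance, so the separable cohort
        reaches the minimal attainable p-value."""
        rng = np.random.default_rng(11)
        y = np.array([0, 1] * 8)
        X = rng.normal(size=(16, 10))
        X[:, 0] = y
        res = M.permutation_test(X, y, n_perm=24, k=3, seed=2)
        assert res.p_value == 1.0 / 25.0
        assert np.mean(res.null_accuracies) < 0.75

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        y = np.array([0, 1] * 6)
        X = rng.normal(size=(12, 15))
        a = M.permutation_test(X, y, n_perm=20, k=5, seed=5)
        b = M.permutation_test(X, y, n_perm=20, k=5, seed=5)
        np.testing.assert_array_equal(a.null_accuracies, b.null_accuracies)
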
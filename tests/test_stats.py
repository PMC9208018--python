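"""Permutation testing, FDR, ROC classification and ANCOVA."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from netpe.stats import ancova_oneway, fdr_bh, logistic_auc, permutation_test

from _oracles import exhaustive_permutation_p, step_up_bh


class TestPermutationTest:
    def test_identical_constant_groups_give_p_one(self):
        a = np.ones((4, 3))
        res = permutation_test(a, a.copy(), n_perm=200, seed=0)
        assert np.all(res.per_roi_stat == 0)
        assert np.all(res.p == 1.0)

    def test_huge_separation_reaches_minimum_p(self, rng):
        a = rng.standard_normal((18, 5)) + 100.0
        b = rng.standard_normal((18, 5))
        res = permutation_test(a, b, n_perm=10_000, seed=1)
        assert np.all(res.p == pytest.approx(1 / 10_001))
        res_raw = permutation_test(a, b, n_perm=10_000, seed=1, plus_one=False)
        assert np.all(res_raw.p == 0.0)

    def test_monte_carlo_matches_exhaustive_oracle(self, rng):
        a = rng.standard_normal((3, 4))
        b = rng.standard_normal((3, 4)) + 1.0
        exact = exhaustive_permutation_p(a, b)  # all C(6,3)=20 partitions
        res = permutation_test(a, b, n_perm=20_000, seed=3, plus_one=False)
        # binomial error at n=20000 for p in [1/20, 1]
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert np.all(np.abs(res.p - exact) < 4 * se + 1e-9)

    def test_invariant_to_group_relabelling(self, rng):
        a = rng.standard_normal((6, 8))
        b = rng.standard_normal((7, 8)) + 0.5
        # swapping which group is "a" flips nothing: |Δmean| is symmetric and
        # partitions are equivalent under complement
        p_ab = permutation_test(a, b, n_perm=4000, seed=9).p
        p_ba = permutation_test(b, a, n_perm=4000, seed=9).p
        np.testing.assert_allclose(p_ab, p_ba, atol=0.02)

    def test_reproducible_and_valid(self, rng):
        a = rng.standard_normal((5, 6))
        b = rng.standard_normal((5, 6))
        r1 = permutation_test(a, b, n_perm=500, seed=7)
        r2 = permutation_test(a, b, n_perm=500, seed=7)
        assert np.array_equal(r1.p, r2.p)
        assert np.all((r1.p > 0) & (r1.p <= 1))
        assert np.all(r1.q >= r1.p - 1e-15)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(np.ones((1, 3)), np.ones((4, 3)))


class TestFdrBh:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_tied_pvalues(self):
        assert fdr_bh([0.2]).tolist() == [0.2]
        np.testing.assert_allclose(fdr_bh([0.3, 0.3, 0.3]), [0.3] * 3)

    def test_matches_independent_step_up(self, rng):
        for _ in range(25):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_bh(p), step_up_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


class TestLogisticAuc:
    def test_perfectly_separated_feature(self):
        rep = logistic_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert rep.auc == 1.0
        rep = logistic_auc([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert rep.auc == 1.0  # model orients the feature
        assert rep.perfect_separation

    def test_constant_feature_gives_half(self):
        rep = logistic_auc(np.full(12, 3.3), [0, 1] * 6)
        assert rep.auc == 0.5

    def test_equals_mannwhitney_identity(self, rng):
        # in-sample logistic scores are monotone in the feature, so the AUC
        # is the midrank U statistic of the (oriented) feature
        for _ in range(50):
            n = int(rng.integers(8, 40))
            x = np.round(rng.standard_normal(n), 1)  # rounding forces ties
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            rep = logistic_auc(x, y)
            u = mannwhitneyu(x[y == 1], x[y == 0]).statistic
            u_auc = u / ((y == 1).sum() * (y == 0).sum())
            direction = u_auc if rep.coefficients[1] >= 0 or rep.perfect_separation else 1 - u_auc
            expected = max(u_auc, 1 - u_auc) if rep.perfect_separation else direction
            assert rep.auc == pytest.approx(expected, abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.standard_normal(30)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        a = logistic_auc(x, y).auc
        b = logistic_auc(np.exp(x), y).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_ci_brackets_auc_and_roc_monotone(self, rng):
        x = rng.standard_normal(40) + np.repeat([0, 1.0], 20)
        y = np.repeat([0, 1], 20)
        rep = logistic_auc(x, y)
        assert 0 <= rep.ci_low <= rep.auc <= rep.ci_high <= 1
        assert np.all(np.diff(rep.roc_points[:, 0]) >= 0)
        assert np.all(np.diff(rep.roc_points[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_auc([1.0, 2.0, 3.0], [1, 1, 1])


class TestAncova:
    def test_covariate_explains_everything(self, rng):
        cov = rng.standard_normal(20)
        y = 2.0 * cov + 1.0
        g = np.repeat([0, 1], 10)
        rep = ancova_oneway(y, g, cov)
        assert rep.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.standard_normal(10)
        g = np.repeat([0, 1], 5)
        cov = rng.standard_normal(10)
        rep = ancova_oneway(y, g, cov)
        # direct least squares via normal equations
        X = np.column_stack([np.ones(10), cov, g])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss_full = ((y - X @ beta) ** 2).sum()
        Xr = X[:, :2]
        beta_r = np.linalg.solve(Xr.T @ Xr, Xr.T @ y)
        rss_red = ((y - Xr @ beta_r) ** 2).sum()
        F = (rss_red - rss_full) / (rss_full / 7)
        assert rep.F == pytest.approx(F, abs=1e-8)
        assert rep.df == (1, 7)
        from scipy.stats import f as fdist

        assert rep.p == pytest.approx(fdist.sf(F, 1, 7), abs=1e-8)

    def test_eta_sq_bounded(self, rng):
        for _ in range(100):
            y = rng.standard_normal(12)
            g = np.repeat([0, 1], 6)
            cov = rng.standard_normal(12)
            rep = ancova_oneway(y, g, cov)
            assert 0.0 <= rep.eta_sq <= 1.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ancova_oneway([1.0] * 4, [0, 0, 1, 1], [0.1, 0.2, 0.3, 0.4])
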
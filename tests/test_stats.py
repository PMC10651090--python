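"""Correlations, paired contrasts, Wilcoxon conventions, OLS and influence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from melanotherm.stats import (
    cooks_distance,
    ols_fit,
    paired_contrast,
    paired_t,
    pearson,
    shapiro_wilk,
    spearman,
    wilcoxon_signed_rank,
)


class TestCorrelations:
    def test_perfect_and_hand_worked(self):
        x = np.arange(10.0)
        r, r2, p = pearson(x, x)
        assert r == pytest.approx(1.0) and p < 1e-10
        r, _, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)
        r, r2, _ = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert r2 == pytest.approx(0.36)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_spearman_monotone_and_hand_worked(self):
        x = np.arange(1, 8.0)
        rho, _ = spearman(x, x ** 3)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)


class TestShapiroGate:
    def test_detects_normal_and_exponential(self):
        # the gate rejects truly normal data at its nominal 5% rate, so
        # retention over 100 replicates sits at ~95 with binomial noise
        normal_ok = sum(
            shapiro_wilk(np.random.default_rng(s).normal(size=500))[1] > 0.05
            for s in range(100))
        assert normal_ok >= 90
        expo_reject = sum(
            shapiro_wilk(np.random.default_rng(s).exponential(size=500))[1] < 0.05
            for s in range(100))
        assert expo_reject >= 95

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.ones(10))


class TestWilcoxon:
    def test_all_one_sided_differences(self):
        # 12 strictly positive differences -> V = 12*13/2 = 78; reversed -> 0
        x = np.arange(1.0, 13.0)
        y = x - np.linspace(0.5, 4.0, 12)
        res = wilcoxon_signed_rank(x, y)
        assert res.statistic == 78.0
        res_rev = wilcoxon_signed_rank(y, x)
        assert res_rev.statistic == 0.0
        # exact two-sided p for a one-sided extreme at n=12
        assert res.p_two_sided == pytest.approx(2 / 2 ** 12)

    def test_hand_enumerated_example(self):
        # d = (+1, -2, +3): ranks (1,2,3), V = 4, exact p = 0.75
        res = wilcoxon_signed_rank([1, 0, 3], [0, 2, 0])
        assert res.statistic == 4.0
        assert res.p_two_sided == pytest.approx(0.75)

    def test_sign_flip_complement(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        v = wilcoxon_signed_rank(x, y).statistic
        v_flip = wilcoxon_signed_rank(y, x).statistic
        n = np.count_nonzero(x - y)
        assert v + v_flip == n * (n + 1) / 2

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_p_matches_full_enumeration(self, n, rng):
        d = rng.normal(size=n)
        assert len(np.unique(np.abs(d))) == n  # tie-free with probability 1
        res = wilcoxon_signed_rank(d, np.zeros(n))
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        vs = [sum(r for r, s in zip(ranks, signs) if s > 0)
              for signs in itertools.product([1, -1], repeat=n)]
        vs = np.array(vs)
        p_le = (vs <= res.statistic).mean()
        p_ge = (vs >= res.statistic).mean()
        assert res.p_two_sided == pytest.approx(min(1.0, 2 * min(p_le, p_ge)))

    def test_matches_scipy_exact(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        d = rng.normal(size=14)
        ours = wilcoxon_signed_rank(d, np.zeros(14))
        ref = scipy_wilcoxon(d, mode="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestPairedT:
    def test_hand_formula(self):
        res = paired_t([1, 2, 3], [0, 0, 0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3))
        assert res.n == 3

    def test_equal_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_two_sided == 1.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            paired_t([2, 3, 4, 5], [1, 2, 3, 4])  # constant nonzero differences

    def test_shift_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = paired_t(x, y)
        b = paired_t(x + 5.0, y + 5.0)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)


class TestPairedContrast:
    def test_gate_follows_normality(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        res = paired_contrast(x, np.zeros(30))
        assert res.test_kind == "t" and res.normality_p >= 0.05
        heavy = rng.standard_cauchy(size=30)
        res2 = paired_contrast(heavy, np.zeros(30))
        assert res2.test_kind == "wilcoxon" and res2.normality_p < 0.05

    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_contrast([1.0, 2.0], [1.0, 2.0])


class TestOLS:
    def test_exact_linear_fit(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [1.0, 3, 5, 7]})
        m = ols_fit("y ~ x", df)
        assert m.params["x"] == pytest.approx(2.0)
        assert m.adjusted_r2 == pytest.approx(1.0)
        np.testing.assert_allclose(m.residuals, 0, atol=1e-10)

    def test_hand_solved_normal_equations(self):
        # 4 points, y = b0 + b1 x solved by hand: X'X b = X'y
        df = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [1.0, 2, 2, 4]})
        m = ols_fit("y ~ x", df)
        assert m.params["Intercept"] == pytest.approx(0.9)
        assert m.params["x"] == pytest.approx(0.9)

    def test_orthogonal_predictor_negative_adjusted_r2(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=200), "y": rng.normal(size=200)})
        m = ols_fit("y ~ x", df)
        assert abs(m.params["x"]) < 0.2
        assert m.adjusted_r2 <= 0.05

    def test_simple_regression_matches_correlation(self, rng):
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        r, r2, _ = pearson(x, y)
        m = ols_fit("y ~ x", pd.DataFrame({"x": x, "y": y}))
        assert m.params["x"] == pytest.approx(r * y.std(ddof=1) / x.std(ddof=1))
        assert m.r2 == pytest.approx(r2)

    def test_underdetermined_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            ols_fit("y ~ x", df)


class TestCooksDistance:
    def test_perfect_fit_all_zero(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3, 4], "y": [1.0, 3, 5, 7, 9]})
        m = ols_fit("y ~ x", df)
        np.testing.assert_allclose(cooks_distance(m), 0.0, atol=1e-16)

    def test_gross_outlier_flagged(self, rng):
        # the outlier sits at the high-leverage end of the design: an
        # interior point at n=12 cannot exceed D=1 however large the shift
        x = np.arange(12.0)
        y = 2 * x + rng.normal(0, 0.1, 12)
        y[11] += 25.0
        m = ols_fit("y ~ x", pd.DataFrame({"x": x, "y": y}))
        d = cooks_distance(m)
        assert d.argmax() == 11 and d[11] > 1.0
        assert m.flagged_influential == [11]

    def test_formula_equals_leave_one_out_refit(self, rng):
        n = 25
        df = pd.DataFrame({
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
        })
        df["y"] = 1 + 2 * df.x1 - df.x2 + rng.normal(size=n)
        m = ols_fit("y ~ x1 + x2", df)
        d_formula = cooks_distance(m)

        X = np.column_stack([np.ones(n), df.x1, df.x2])
        y = df.y.to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        yhat = X @ beta
        p = X.shape[1]
        s2 = ((y - yhat) ** 2).sum() / (n - p)
        d_loo = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            beta_i = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            d_loo[i] = ((yhat - X @ beta_i) ** 2).sum() / (p * s2)
        np.testing.assert_allclose(d_formula, d_loo, atol=1e-10)

    def test_matches_statsmodels(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=15)})
        df["y"] = df.x + rng.normal(size=15)
        m = ols_fit("y ~ x", df)
        np.testing.assert_allclose(cooks_distance(m), m.cooks_distances, atol=1e-12)
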
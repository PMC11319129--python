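"""Two-way ANOVA, LSD letters, correlation matrices and trend fits."""
import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rhizostoich import lsd_pairwise, pearson_matrix, trend_fit, two_way_anova
from rhizostoich.errors import DesignError, DomainError
from rhizostoich.stats import significance_stars


def _statsmodels_anova(y, a, b):
    """Independent route: OLS + anova_lm (Type II; equals Type I when balanced)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "A": np.asarray(a).astype(str),
                       "B": np.asarray(b).astype(str)})
    fit = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    return sm.stats.anova_lm(fit, typ=2)


class TestTwoWayAnova:
    def test_hand_computed_2x2(self):
        """2x2, n=2/cell, cells {1,2},{3,4},{5,6},{7,8}: the sums of squares
        decompose to SS_A=32, SS_B=8, SS_AB=0, SS_E=2 by hand."""
        y = [1, 2, 3, 4, 5, 6, 7, 8]
        a = ["a1"] * 4 + ["a2"] * 4
        b = ["b1", "b1", "b2", "b2"] * 2
        tab = two_way_anova(y, a, b)
        assert tab["A"]["F"] == pytest.approx(64.0)
        assert tab["B"]["F"] == pytest.approx(16.0)
        assert tab["A:B"]["F"] == pytest.approx(0.0, abs=1e-12)
        assert tab["Residual"]["df"] == 4
        assert tab["A"]["ss"] == pytest.approx(32.0)
        # dfs partition n - 1
        assert sum(t["df"] for t in tab.terms.values()) == len(y) - 1

    def test_constant_response_flags_nan(self):
        with pytest.warns(UserWarning, match="zero residual variance"):
            tab = two_way_anova([3.0] * 8, ["a1"] * 4 + ["a2"] * 4,
                                ["b1", "b1", "b2", "b2"] * 2)
        assert np.isnan(tab["A"]["F"])
        assert tab["A"]["ss"] == pytest.approx(0.0)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        a = np.repeat(["a1", "a2"], 6)
        b = np.tile(np.repeat(["b1", "b2", "b3"], 2), 2)
        tab1 = two_way_anova(y, a, b)
        perm = rng.permutation(12)
        tab2 = two_way_anova(y[perm], a[perm], b[perm])
        for term in tab1.terms:
            assert tab1[term]["ss"] == pytest.approx(tab2[term]["ss"], rel=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_statsmodels_on_random_balanced(self, seed):
        rng = np.random.default_rng(seed)
        na, nb, r = rng.integers(2, 4), rng.integers(2, 5), rng.integers(2, 4)
        a = np.repeat([f"a{i}" for i in range(na)], nb * r)
        b = np.tile(np.repeat([f"b{j}" for j in range(nb)], r), na)
        y = rng.normal(size=na * nb * r)
        tab = two_way_anova(y, a, b)
        ref = _statsmodels_anova(y, a, b)
        assert tab["A"]["ss"] == pytest.approx(ref.loc["C(A)", "sum_sq"], rel=1e-9)
        assert tab["B"]["ss"] == pytest.approx(ref.loc["C(B)", "sum_sq"], rel=1e-9)
        assert tab["A:B"]["ss"] == pytest.approx(ref.loc["C(A):C(B)", "sum_sq"], rel=1e-9)
        assert tab["A"]["p"] == pytest.approx(ref.loc["C(A)", "PR(>F)"], rel=1e-9)

    def test_balanced_ss_partition(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=30)
        a = np.repeat(["a1", "a2", "a3"], 10)
        b = np.tile(np.repeat(["b1", "b2"], 5), 3)
        tab = two_way_anova(y, a, b)
        total = ((y - y.mean()) ** 2).sum()
        parts = sum(t["ss"] for t in tab.terms.values())
        assert parts == pytest.approx(total, rel=1e-9)

    def test_empty_cell_raises(self):
        with pytest.raises(DesignError, match="empty"):
            two_way_anova([1, 2, 3], ["a1", "a1", "a2"], ["b1", "b2", "b1"])

    def test_unbalanced_fallback_warns(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=9)
        a = ["a1"] * 5 + ["a2"] * 4
        b = ["b1", "b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"]
        with pytest.warns(UserWarning, match="unbalanced"):
            tab = two_way_anova(y, a, b)
        ref = _statsmodels_anova(y, a, b)
        assert tab["A"]["ss"] == pytest.approx(ref.loc["C(A)", "sum_sq"], rel=1e-9)


class TestLSD:
    def test_equal_means_share_letter(self):
        disp = lsd_pairwise({"g1": 5.0, "g2": 5.0}, 3, mse=1.0, df_e=4)
        assert disp.pairwise.loc[0, "p"] == pytest.approx(1.0)
        assert disp.letters["g1"] == disp.letters["g2"]

    def test_critical_difference(self):
        """LSD = t(0.975, 4) * sqrt(2 * MSE / n) ~= 2.776 * 0.7071 ~= 1.963."""
        lsd = sps.t.ppf(0.975, 4) * np.sqrt(2 * 0.5 / 2)
        assert lsd == pytest.approx(1.963, abs=5e-4)
        just_below = lsd_pairwise({"g1": 0.0, "g2": lsd * 0.999}, 2, 0.5, 4)
        just_above = lsd_pairwise({"g1": 0.0, "g2": lsd * 1.001}, 2, 0.5, 4)
        assert not just_below.pairwise.loc[0, "significant"]
        assert just_above.pairwise.loc[0, "significant"]

    def test_letters_against_bruteforce(self):
        means = {"g1": 1.0, "g2": 2.0, "g3": 10.0}
        disp = lsd_pairwise(means, 3, mse=0.5, df_e=6)
        # brute-force pairwise significance
        sig = {}
        for g, h in itertools.combinations(means, 2):
            t = abs(means[g] - means[h]) / np.sqrt(0.5 * (2 / 3))
            sig[(g, h)] = 2 * sps.t.sf(t, 6) < 0.05
        for (g, h), s in sig.items():
            shared = set(disp.letters[g]) & set(disp.letters[h])
            assert bool(shared) == (not s)

    @pytest.mark.parametrize("seed", range(20))
    def test_letter_partition_invariant(self, seed):
        """Groups share a letter exactly when their pairwise p >= alpha."""
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 7)
        means = {f"g{i}": float(rng.normal(0, 2)) for i in range(k)}
        disp = lsd_pairwise(means, 3, mse=float(rng.uniform(0.1, 3)), df_e=10)
        pw = disp.pairwise.set_index(["group1", "group2"])
        for g, h in itertools.combinations(means, 2):
            p = pw.loc[(g, h), "p"]
            shared = bool(set(disp.letters[g]) & set(disp.letters[h]))
            assert shared == (p >= disp.alpha)

    def test_single_group(self):
        disp = lsd_pairwise({"g1": 1.0}, 3, 1.0, 4)
        assert len(disp.pairwise) == 0
        assert disp.letters["g1"] == "a"

    def test_bad_inputs(self):
        with pytest.raises(DomainError):
            lsd_pairwise({"g1": 1.0, "g2": 2.0}, 3, mse=0.0, df_e=4)
        with pytest.raises(DomainError):
            lsd_pairwise({"g1": 1.0, "g2": 2.0}, 3, mse=1.0, df_e=0)


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10.0)
        r, p = pearson_matrix({"x": x, "y": 2 * x, "z": -x})
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)
        assert p.loc["x", "y"] < 1e-12
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = pearson_matrix({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        assert np.isnan(r.loc["x", "c"])

    def test_type_one_error_calibration(self):
        """Independent normals: the p < 0.05 rate sits near 0.05."""
        rng = np.random.default_rng(42)
        n, reps = 50, 500
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        hits = 0
        for i in range(reps):
            _, p = sps.pearsonr(x[i], y[i])
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.2) == ""


class TestTrendFit:
    def test_exact_linear(self):
        x = np.arange(6.0)
        fit = trend_fit(x, 3 * x + 1, order=1)
        assert fit.coefficients == pytest.approx((1.0, 3.0))
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_quadratic(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        fit = trend_fit(x, x ** 2, order=2)
        assert fit.coefficients[2] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_symmetric_data_zero_slope(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        fit = trend_fit(x, x ** 2, order=1)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-12)

    def test_r_squared_equals_pearson_r2(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 4, 40)
        y = 1.5 * x + rng.normal(size=40)
        fit = trend_fit(x, y, order=1)
        r = sps.pearsonr(x, y).statistic
        assert fit.r_squared - r ** 2 == pytest.approx(0.0, abs=1e-12)

    def test_confidence_band_covers_fit(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 4, 60)
        y = 2 * x + rng.normal(size=60)
        fit = trend_fit(x, y, order=1)
        lo, hi = fit.confidence_band([1.0, 2.0, 3.0])
        pred = fit.predict([1.0, 2.0, 3.0])
        assert np.all(lo < pred) and np.all(pred < hi)

    def test_insufficient_x(self):
        with pytest.raises(DomainError):
            trend_fit([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], order=1)
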
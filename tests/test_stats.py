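"""Elementary statistics against closed forms, brute-force oracles, and the
independent scipy/statsmodels implementations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from crcscreen.stats import (ZeroVarianceError, anova_oneway, bh_adjust,
                             linear_trend_test, pearson_test, t_test_paired,
                             t_test_unpaired, tukey_hsd)


def t_sf_oracle(t, df):
    """Student-t upper tail via the regularized incomplete beta function —
    an evaluation path independent of scipy.stats.t."""
    x = df / (df + t * t)
    p = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return p if t >= 0 else 1.0 - p


class TestPearson:
    def test_perfect_linear(self):
        assert pearson_test([1, 2, 3, 4], [2, 4, 6, 8]).estimate == 1.0
        assert pearson_test([1, 2, 3, 4], [4, 3, 2, 1]).estimate == -1.0

    def test_seeded_vs_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        n = 20
        # direct-summation covariance/variance oracle
        sx = x.sum()
        sy = y.sum()
        sxy = (x * y).sum()
        sxx = (x * x).sum()
        syy = (y * y).sum()
        r_o = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx * sx) * (n * syy - sy * sy))
        t_o = r_o * math.sqrt((n - 2) / (1 - r_o**2))
        p_o = 2 * t_sf_oracle(abs(t_o), n - 2)
        res = pearson_test(x, y)
        assert res.estimate == pytest.approx(r_o, abs=1e-12)
        assert res.p_value == pytest.approx(p_o, abs=1e-10)
        # independent library cross-check
        lib = sps.pearsonr(x, y)
        assert res.estimate == pytest.approx(lib.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(lib.pvalue, abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, np.nan, 10]
        res = pearson_test(x, y)
        assert res.n == 3
        assert res.estimate == pytest.approx(1.0)

    @pytest.mark.parametrize("x,y,err", [
        ([1, 2], [1, 2], "pairs"),
        ([1, 2, 3], [1, 2], "mismatch"),
        ([1, 1, 1], [1, 2, 3], "variance"),
    ])
    def test_errors_distinguish_cause(self, x, y, err):
        with pytest.raises(ValueError, match=err):
            pearson_test(x, y)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r0 = pearson_test(x, y).estimate
        assert pearson_test(a * x + b, y).estimate == pytest.approx(
            r0, abs=1e-12)
        assert pearson_test(-x, y).estimate == pytest.approx(-r0, abs=1e-12)


class TestTTests:
    def test_identical_groups(self):
        res = t_test_unpaired([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0
        assert res.p_value == 1

    def test_zero_variance_both_errors(self):
        with pytest.raises(ZeroVarianceError):
            t_test_unpaired([0, 0, 0, 0], [1, 1, 1, 1])

    def test_seeded_vs_formula_oracle(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1.5, 10)
        for pooled in (True, False):
            res = t_test_unpaired(a, b, pooled=pooled)
            na, nb = 10, 10
            va, vb = a.var(ddof=1), b.var(ddof=1)
            if pooled:
                se = math.sqrt(((na - 1) * va + (nb - 1) * vb)
                               / (na + nb - 2) * (1 / na + 1 / nb))
                df = na + nb - 2
            else:
                se = math.sqrt(va / na + vb / nb)
                df = (va / na + vb / nb) ** 2 / (
                    (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            t_o = (a.mean() - b.mean()) / se
            assert res.statistic == pytest.approx(t_o, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)
            assert res.p_value == pytest.approx(
                2 * t_sf_oracle(abs(t_o), df), abs=1e-10)
            lib = sps.ttest_ind(a, b, equal_var=pooled)
            assert res.p_value == pytest.approx(lib.pvalue, abs=1e-12)

    def test_paired_equals_one_sample_on_differences(self):
        res = t_test_paired([1, 2, 3], [2, 3, 5])
        d = np.array([1, 1, 2])
        t_o = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        assert res.statistic == pytest.approx(t_o, abs=1e-12)
        assert res.estimate == pytest.approx(d.mean())

    def test_paired_seeded_vs_oracle(self):
        rng = np.random.default_rng(14)
        pre = rng.normal(size=14)
        post = pre + rng.normal(0.3, 0.6, 14)
        res = t_test_paired(pre, post)
        lib = sps.ttest_rel(post, pre)
        assert res.statistic == pytest.approx(lib.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(lib.pvalue, abs=1e-10)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_paired_zero_variance_errors(self):
        with pytest.raises(ZeroVarianceError):
            t_test_paired([1, 2, 3], [1, 2, 3])
        with pytest.raises(ZeroVarianceError):
            t_test_paired([1, 2, 3], [2, 3, 4])


class TestAnovaTrendTukey:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=8)
        b = rng.normal(0.5, 1, 8)
        F = anova_oneway([a, b])
        t = t_test_unpaired(a, b, pooled=True)
        assert F.statistic == pytest.approx(t.statistic**2, abs=1e-10)
        assert F.p_value == pytest.approx(t.p_value, abs=1e-10)

    def test_seeded_vs_sum_of_squares_oracle(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(m, 1, 6) for m in (0, 0.3, 0.6, 1.0)]
        res = anova_oneway(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F_o = (ssb / 3) / (ssw / (24 - 4))
        assert res.statistic == pytest.approx(F_o, abs=1e-10)
        lib = sps.f_oneway(*groups)
        assert res.p_value == pytest.approx(lib.pvalue, abs=1e-12)

    def test_all_identical_defines_f_zero(self):
        res = anova_oneway([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_trend_equal_means_null(self):
        g = np.array([1.0, 2.0, 3.0])
        res = linear_trend_test([g, g + 0.0, g + 0.0, g + 0.0])
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_trend_zero_mse_errors(self):
        groups = [[m, m] for m in (1.0, 2.0, 3.0, 4.0)]
        with pytest.raises(ZeroVarianceError):
            linear_trend_test(groups)

    def test_trend_needs_three_groups(self):
        with pytest.raises(ValueError, match="3"):
            linear_trend_test([[1, 2], [3, 4]])

    def test_trend_matches_regression_slope_on_balanced_design(self):
        # oracle: OLS slope t test of value on group score, coded directly
        rng = np.random.default_rng(8)
        groups = [rng.normal(0.2 * s, 1, 10) for s in (1, 2, 3, 4)]
        res = linear_trend_test(groups)
        x = np.repeat([1.0, 2.0, 3.0, 4.0], 10)
        y = np.concatenate(groups)
        xc = x - x.mean()
        beta = (xc @ y) / (xc @ xc)
        resid = y - y.mean() - beta * xc
        # error df matches the trend test (within-group variance model)
        gm = np.repeat([g.mean() for g in groups], 10)
        sse = ((y - gm) ** 2).sum()
        df = 40 - 4
        se = math.sqrt(sse / df / (xc @ xc))
        t_o = beta / se
        p_o = 2 * t_sf_oracle(abs(t_o), df)
        assert res.p_value == pytest.approx(p_o, abs=1e-8)

    def test_tukey_identical_and_shifted_groups(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 12)
        b = a.copy()  # identical group
        c = rng.normal(10, 1, 12)  # shifted by 10 sd
        pairs = tukey_hsd([a, b, c])
        by = {(t.group1, t.group2): t for t in pairs}
        assert by[(0, 1)].p_value > 0.9
        assert by[(0, 2)].p_value < 0.001
        assert by[(1, 2)].p_value < 0.001
        lib = sps.tukey_hsd(a, b, c)
        for (i, j), t in by.items():
            assert t.p_value == pytest.approx(lib.pvalue[i, j], abs=1e-6)

    def test_tukey_requires_three_groups(self):
        with pytest.raises(ValueError):
            tukey_hsd([[1, 2, 3], [2, 3, 4]])


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_and_bounds(self):
        rng = np.random.default_rng(10)
        p = np.concatenate([rng.uniform(size=30), [1.0]])
        adj = bh_adjust(p)
        _, lib, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, lib, atol=1e-12)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
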
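"""Survival primitives against risk-set enumeration oracles, lifelines, and
their rank-invariance properties."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from crcscreen.simulate import gen_survival_cohort
from crcscreen.survival import (km_curve, logrank_counts, logrank_test,
                                optimal_cutoff, stratified_survival)

# 8-patient worked fixture; O1/E1/V enumerated by hand (exact fractions:
# O1 = 2, E1 = 83/30, V = 1091/900)
FIX_T1, FIX_E1 = [5, 8, 12, 20], [0, 1, 1, 0]
FIX_T2, FIX_E2 = [3, 6, 10, 15], [1, 1, 0, 1]


class TestKM:
    def test_three_events_no_censoring(self):
        curve = km_curve([1, 2, 3], [1, 1, 1])
        assert curve["survival"].tolist() == pytest.approx(
            [1.0, 2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        curve = km_curve([4, 5, 6], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_seeded_vs_risk_set_oracle_and_lifelines(self, rng):
        time = rng.uniform(1, 50, 10)
        event = rng.integers(0, 2, 10)
        event[0] = 1
        curve = km_curve(time, event)
        # explicit risk-set product oracle
        s = 1.0
        expect = {}
        for t in np.sort(np.unique(time[event == 1])):
            d = int(((time == t) & (event == 1)).sum())
            n = int((time >= t).sum())
            s *= 1 - d / n
            expect[t] = s
        for t, se in expect.items():
            got = curve.loc[curve["time"] == t, "survival"].iloc[0]
            assert got == pytest.approx(se, abs=1e-12)
        kmf = KaplanMeierFitter().fit(time, event)
        for t, se in expect.items():
            assert kmf.predict(t) == pytest.approx(se, abs=1e-10)

    def test_monotone_and_bounded(self, rng):
        time = rng.uniform(1, 20, 50)
        event = rng.integers(0, 2, 50)
        s = km_curve(time, event)["survival"]
        assert (s.diff().dropna() <= 1e-12).all()
        assert s.between(0, 1).all()

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            km_curve([], [])
        with pytest.raises(ValueError):
            km_curve([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [2, 4, 6, 8]
        e = [1, 0, 1, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.hr == pytest.approx(1.0, abs=1e-12)

    def test_worked_fixture_exact(self):
        O1, E1, V = logrank_counts(FIX_T1, FIX_E1, FIX_T2, FIX_E2)
        assert O1 == pytest.approx(2.0, abs=1e-12)
        assert E1 == pytest.approx(83 / 30, abs=1e-12)
        assert V == pytest.approx(1091 / 900, abs=1e-12)
        res = logrank_test(FIX_T1, FIX_E1, FIX_T2, FIX_E2)
        assert res.chi2 == pytest.approx((2 - 83 / 30) ** 2 / (1091 / 900),
                                         abs=1e-12)
        assert res.hr == pytest.approx(
            np.exp((2 - 83 / 30) / (1091 / 900)), abs=1e-12)
        ll = ll_logrank(FIX_T1, FIX_T2, FIX_E1, FIX_E2)
        assert res.chi2 == pytest.approx(ll.test_statistic, abs=1e-10)
        assert res.p == pytest.approx(ll.p_value, abs=1e-10)

    def test_time_scaling_invariance(self):
        a = logrank_test(FIX_T1, FIX_E1, FIX_T2, FIX_E2)
        b = logrank_test([t * 12 for t in FIX_T1], FIX_E1,
                         [t * 12 for t in FIX_T2], FIX_E2)
        assert (a.chi2, a.p, a.hr) == pytest.approx((b.chi2, b.p, b.hr))

    def test_group_swap_symmetry(self):
        a = logrank_test(FIX_T1, FIX_E1, FIX_T2, FIX_E2)
        b = logrank_test(FIX_T2, FIX_E2, FIX_T1, FIX_E1)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)
        assert a.observed_minus_expected == pytest.approx(
            -b.observed_minus_expected, abs=1e-12)
        assert a.hr * b.hr == pytest.approx(1.0, abs=1e-10)

    def test_zero_event_group_named(self):
        with pytest.raises(ValueError, match="group 2"):
            logrank_test([1, 2], [1, 1], [3, 4], [0, 0])


class TestOptimalCutoff:
    def test_perfect_separation(self):
        # low covariate cluster dies early, high cluster late; within-cluster
        # covariate order scrambled so only the cluster gap is informative
        time = [1, 2, 3, 4, 5, 30, 40, 50, 60, 70]
        event = [1] * 10
        cov = [0.3, 0.1, 0.4, 0.0, 0.2, 5.2, 5.0, 5.4, 5.1, 5.3]
        c, comp = optimal_cutoff(time, event, cov, minprop=0.1)
        assert 0.4 <= c < 5.0
        assert comp.hr < 1  # high covariate, late events
        assert comp.selection_bias

    def test_equals_brute_force_scan(self, rng):
        n = 60
        cov = rng.normal(size=n)
        time = rng.exponential(20, n) + 0.1
        event = rng.integers(0, 2, n)
        event[:4] = 1
        c, comp = optimal_cutoff(time, event, cov, minprop=0.1)
        # brute force: evaluate logrank_test at every admissible split
        best = None
        for cand in np.unique(cov):
            high = cov > cand
            if min(high.sum(), (~high).sum()) < 0.1 * n:
                continue
            if event[high].sum() == 0 or event[~high].sum() == 0:
                continue
            r = logrank_test(np.asarray(time)[high], event[high],
                             np.asarray(time)[~high], event[~high])
            if best is None or r.chi2 > best[1]:
                best = (cand, r.chi2)
        assert c == pytest.approx(best[0])
        assert comp.chi2 == pytest.approx(best[1], abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        n = 40
        cov = rng.normal(size=n)
        time = rng.exponential(20, n) + 0.1
        event = np.ones(n, dtype=int)
        c1, comp1 = optimal_cutoff(time, event, cov)
        c2, comp2 = optimal_cutoff(time, event, np.exp(cov))
        assert comp1.chi2 == pytest.approx(comp2.chi2, abs=1e-10)
        assert comp1.hr == pytest.approx(comp2.hr, abs=1e-10)
        assert c2 == pytest.approx(np.exp(c1), abs=1e-12)

    def test_minprop_near_half_restricts_to_median_splits(self):
        time = [5, 10, 15, 20, 25, 30, 35, 40, 45, 50]
        event = [1] * 10
        cov = list(range(10))
        c, comp = optimal_cutoff(time, event, cov, minprop=0.49)
        assert comp.n_high == 5 and comp.n_low == 5

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            optimal_cutoff([1] * 12, [1] * 12, [2.0] * 12)


class TestStratified:
    def test_interaction_sign_flip(self):
        frame = gen_survival_cohort(n_per_stratum=150, beta_wt=-0.8,
                                    beta_mut=0.8, seed=17)
        res = stratified_survival(frame)
        assert res["wt"].evaluable and res["mut"].evaluable
        assert res["wt"].comparison.hr < 1.0
        assert res["mut"].comparison.hr > 1.0

    def test_single_stratum_matches_optimal_cutoff(self):
        frame = gen_survival_cohort(n_per_stratum=60, seed=3)
        sub = frame[frame["stratum"] == "wt"].copy()
        res = stratified_survival(sub)
        c, comp = optimal_cutoff(sub["time"], sub["event"],
                                 sub["expression"])
        assert res["wt"].cutoff == pytest.approx(c)
        assert res["wt"].comparison.chi2 == pytest.approx(comp.chi2)

    def test_too_small_stratum_reported_not_fatal(self):
        frame = gen_survival_cohort(n_per_stratum=60, seed=3)
        small = frame[frame["stratum"] == "mut"].head(4)
        mixed = pd.concat([frame[frame["stratum"] == "wt"], small])
        res = stratified_survival(mixed)
        assert res["wt"].evaluable
        assert not res["mut"].evaluable
        assert res["mut"].reason
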
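import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habhet.survival import (
    cox_hr,
    km_estimate,
    logrank,
    rmst,
    rmst_difference,
    survival_report,
)


def weibull_cohort(n, shape, scale, log_hr=0.0, prevalence=0.3,
                   censor=(60.0, 120.0), seed=0):
    rng = np.random.default_rng(seed)
    group = (rng.uniform(size=n) < prevalence).astype(int)
    u = rng.uniform(size=n)
    t_event = scale * (-np.log(u) / np.exp(log_hr * group)) ** (1 / shape)
    c = rng.uniform(*censor, size=n)
    return pd.DataFrame({
        "time": np.minimum(t_event, c),
        "event": (t_event <= c).astype(int),
        "group": group,
    })


class TestKM:
    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([10, 20, 30], [0, 0, 0])
        assert km.survival_at(29.9) == 1.0
        assert np.isnan(km.median)

    def test_single_event_drops_to_zero(self):
        km = km_estimate([5.0], [1])
        assert km.survival_at(4.9) == 1.0
        assert km.survival_at(5.0) == 0.0
        assert km.median == pytest.approx(5.0)

    def test_exponential_median_matches_closed_form(self):
        lam = 0.02
        rng = np.random.default_rng(1)
        t = rng.exponential(1 / lam, 500)
        km = km_estimate(t, np.ones(500, int))
        assert km.median == pytest.approx(np.log(2) / lam, rel=0.10)
        assert km.median_ci[0] < km.median < km.median_ci[1]

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])


class TestRMST:
    def test_no_events_gives_tau(self):
        value, _ = rmst([100, 120, 140], [0, 0, 0], tau=60)
        assert value == pytest.approx(60.0)

    def test_exponential_closed_form(self):
        lam, tau, n = 1 / 50.0, 36.0, 2000
        rng = np.random.default_rng(2)
        t = rng.exponential(1 / lam, n)
        value, (lo, hi) = rmst(t, np.ones(n, int), tau)
        expected = (1 - np.exp(-lam * tau)) / lam
        assert value == pytest.approx(expected, rel=0.05)
        assert lo < value < hi

    def test_monotone_in_tau_and_bounded(self):
        df = weibull_cohort(300, 1.3, 90, seed=3)
        values = [rmst(df["time"], df["event"], tau)[0] for tau in (12, 36, 60)]
        assert values == sorted(values)
        assert all(v <= tau for v, tau in zip(values, (12, 36, 60)))

    def test_group_difference_statistic(self):
        df = weibull_cohort(400, 1.3, 90, log_hr=np.log(3.0), seed=4)
        g1, g0 = df[df.group == 1], df[df.group == 0]
        out = rmst_difference(g1["time"], g1["event"], g0["time"], g0["event"], 36)
        assert out["difference"] < 0      # higher hazard, shorter survival
        assert out["p"] < 0.05


class TestLogrank:
    def test_cloned_groups_p_one(self):
        t = [5, 10, 15, 20, 25.0]
        e = [1, 0, 1, 1, 0]
        stat, p = logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(300):
            t = rng.exponential(50, 60)
            e = (rng.uniform(size=60) < 0.7).astype(int)
            g = rng.uniform(size=60) < 0.5
            pvals.append(logrank(t[g], e[g], t[~g], e[~g])[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_separation_detected(self):
        df = weibull_cohort(200, 1.3, 120, log_hr=np.log(5.0), prevalence=0.5,
                            seed=6)
        g1, g0 = df[df.group == 1], df[df.group == 0]
        _, p = logrank(g1["time"], g1["event"], g0["time"], g0["event"])
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([], [], [1.0], [1])


class TestCox:
    def test_parameter_recovery_hr_2_2(self):
        true_hr = 2.2
        covered = 0
        for rep in range(40):
            df = weibull_cohort(275, 1.3, 110, log_hr=np.log(true_hr),
                                prevalence=0.25, seed=100 + rep)
            out = cox_hr(df, "time", "event", ["group"])
            if out.loc["group", "lo95"] <= true_hr <= out.loc["group", "hi95"]:
                covered += 1
        assert covered >= 34  # ~95% nominal coverage, binomial slack

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for rep in range(30):
            df = weibull_cohort(200, 1.3, 100, log_hr=0.0, prevalence=0.5,
                                seed=200 + rep)
            out = cox_hr(df, "time", "event", ["group"])
            if out.loc["group", "lo95"] <= 1.0 <= out.loc["group", "hi95"]:
                covered += 1
        assert covered >= 24

    def test_collinear_covariates_rejected(self):
        df = weibull_cohort(100, 1.3, 90, seed=7)
        df["group2"] = df["group"]
        with pytest.raises(ValueError, match="collinear"):
            cox_hr(df, "time", "event", ["group", "group2"])


class TestReport:
    def test_stratified_report_fields(self):
        df = weibull_cohort(250, 1.3, 110, log_hr=np.log(2.2), prevalence=0.3,
                            seed=8)
        rep = survival_report(df, "group", taus=(36.0, 60.0))
        assert rep["logrank_p"] < 0.05
        assert rep["cox"]["HR"] > 1.0
        assert rep["rmst_36"]["rmst_a"] <= 36.0
        assert rep["rmst_60"]["rmst_b"] <= 60.0
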
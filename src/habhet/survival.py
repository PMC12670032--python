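"""Survival-risk stratification: Kaplan-Meier, log-rank, RMST/RMRFT, Cox.

Times are in months. Restricted means are reported at tau = 36 and 60 months
(the 3- and 5-year windows); the restricted mean is the area under the
Kaplan-Meier curve from 0 to tau, with variance from the integrated
Greenwood formula. Cox fits are univariable by default with Efron tie
handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import median_survival_times, restricted_mean_survival_time
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_TAUS = (36.0, 60.0)


@dataclass
class KMResult:
    """Kaplan-Meier estimate with Greenwood CIs and median survival."""

    fitter: KaplanMeierFitter
    median: float          # NaN when S(t) never reaches 0.5
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        return float(self.fitter.predict(t))


def km_estimate(times, events, label: str = "KM") -> KMResult:
    """Product-limit estimator with Brookmeyer-Crowley median CI.

    The median and its CI are reported as NaN (the table convention ``NA``)
    when the curve never drops to 0.5.
    """
    t = np.asarray(times, np.float64)
    e = np.asarray(events).astype(int)
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(t, e)
    med = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    if not np.isfinite(med):
        med, lo, hi = np.nan, np.nan, np.nan
    return KMResult(kmf, med, (lo, hi))


def rmst(times, events, tau: float) -> tuple[float, tuple[float, float]]:
    """Restricted mean survival time to tau with a 95% CI.

    Area under the KM curve on [0, tau]; variance by the integrated
    Greenwood formula. When tau exceeds the last observed time the curve is
    truncated at that time (warned and logged).
    """
    t = np.asarray(times, np.float64)
    e = np.asarray(events).astype(int)
    if t.size == 0:
        raise ValueError("empty group")
    if tau > t.max():
        logger.warning("tau=%.1f beyond last observed time %.1f; truncating", tau, t.max())
        tau = float(t.max())
    kmf = KaplanMeierFitter().fit(t, e)
    value = float(restricted_mean_survival_time(kmf, t=tau))

    # integrated-Greenwood variance:
    #   Var = sum_i A_i^2 d_i / (n_i (n_i - d_i)),  A_i = area under KM on [t_i, tau]
    table = kmf.event_table
    times = table.index.to_numpy(np.float64)
    d = table["observed"].to_numpy(np.float64)
    n_at_risk = table["at_risk"].to_numpy(np.float64)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()

    # area under the step function from each event time to tau
    grid = np.r_[times[times < tau], tau]
    seg = np.diff(grid)
    s_on_seg = surv[times < tau]
    area_from = np.r_[np.cumsum((seg * s_on_seg)[::-1])[::-1], 0.0]
    var = 0.0
    sel = (times < tau) & (d > 0)
    for ti, di, ni, ai in zip(times[sel], d[sel], n_at_risk[sel],
                              area_from[:-1][sel[times < tau]]):
        if ni > di:
            var += ai**2 * di / (ni * (ni - di))
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.975)
    return value, (value - z * se, value + z * se)


def rmst_difference(times_a, events_a, times_b, events_b, tau: float) -> dict:
    """Between-group difference in RMST with a normal-approximation P value."""
    va, (loa, hia) = rmst(times_a, events_a, tau)
    vb, (lob, hib) = rmst(times_b, events_b, tau)
    z975 = stats.norm.ppf(0.975)
    sea = (hia - loa) / (2 * z975)
    seb = (hib - lob) / (2 * z975)
    diff = va - vb
    se = float(np.hypot(sea, seb))
    z = diff / se if se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return {"rmst_a": va, "rmst_b": vb, "difference": float(diff), "se": se, "p": p}


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, P value)."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be nonempty")
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_hr(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
) -> pd.DataFrame:
    """Univariable/multivariable Cox fit; rows per covariate with HR, 95% CI, P.

    Uses the Efron approximation for ties. Events-per-covariate below 10 is
    allowed but warned about; complete separation surfaces as a convergence
    error from the partial-likelihood fit.
    """
    n_events = int(df[event_col].sum())
    if n_events < 10 * len(covariates):
        logger.warning("only %d events for %d covariate(s)", n_events, len(covariates))
    sub = df[[duration_col, event_col, *covariates]]
    for i, a in enumerate(covariates):
        for b in covariates[i + 1:]:
            if np.allclose(sub[a], sub[b]):
                raise ValueError(f"collinear covariates: {a!r} and {b!r} are identical")
    cph = CoxPHFitter()
    cph.fit(sub, duration_col=duration_col, event_col=event_col)
    out = pd.DataFrame({
        "HR": np.exp(cph.params_),
        "lo95": np.exp(cph.confidence_intervals_.iloc[:, 0]),
        "hi95": np.exp(cph.confidence_intervals_.iloc[:, 1]),
        "p": cph.summary["p"],
    })
    out.index.name = "covariate"
    return out


def survival_report(records: pd.DataFrame, group_col: str, taus=DEFAULT_TAUS) -> dict:
    """Stratified summary for one endpoint table with columns
    ``time``/``event``: per-group medians, log-rank, RMST at each tau, Cox HR."""
    groups = sorted(records[group_col].unique(), reverse=True)
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    g1 = records[records[group_col] == groups[0]]
    g0 = records[records[group_col] == groups[1]]
    out: dict = {"groups": [str(groups[0]), str(groups[1])]}
    for tag, g in (("pos", g1), ("neg", g0)):
        km = km_estimate(g["time"], g["event"])
        out[f"median_{tag}"] = km.median
        out[f"median_{tag}_ci"] = km.median_ci
    stat, p = logrank(g1["time"], g1["event"], g0["time"], g0["event"])
    out["logrank_chi2"], out["logrank_p"] = stat, p
    for tau in taus:
        cmp = rmst_difference(g1["time"], g1["event"], g0["time"], g0["event"], tau)
        out[f"rmst_{int(tau)}"] = cmp
    df = records.assign(_g=(records[group_col] == groups[0]).astype(int))
    hr = cox_hr(df, "time", "event", ["_g"])
    out["cox"] = {
        "HR": float(hr.loc["_g", "HR"]),
        "lo95": float(hr.loc["_g", "lo95"]),
        "hi95": float(hr.loc["_g", "hi95"]),
        "p": float(hr.loc["_g", "p"]),
    }
    return out
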
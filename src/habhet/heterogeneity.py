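"""Heterogeneity quantification: coefficient of variation across habitats.

For every radiomic feature, heterogeneity within a region is the coefficient
of variation of that feature across the region's habitats,

    CV = SD_i / |mean_i|,

with sample SD (ddof = 1). A value of 0 indicates complete homogeneity;
larger values indicate more uneven feature distributions across habitats.
Applied to the four regions (intratumoral, Peri3, Peri5, Peri7) x 428
features this yields the 1712-entry per-case ITH/PTH signature.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEAN_EPS = 1e-8
REGION_ORDER = ("ITH", "Peri3", "Peri5", "Peri7")
N_HETEROGENEITY_FEATURES = 1712


def cv(values, ddof: int = 1, eps: float = MEAN_EPS) -> float:
    """Coefficient of variation SD/|mean| of feature values across habitats.

    Missing entries (NaN) are excluded pairwise. Returns NaN (missing) when
    fewer than 2 values survive or the mean magnitude is below ``eps``
    (guarding against explosive CVs on near-zero means).
    """
    v = np.asarray(values, np.float64)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return np.nan
    m = v.mean()
    if abs(m) < eps:
        return np.nan
    return float(v.std(ddof=ddof) / abs(m))


def _cv_columns(data: np.ndarray, ddof: int = 1, eps: float = MEAN_EPS) -> np.ndarray:
    """Column-wise CV of a habitats x features matrix (same semantics as
    :func:`cv`, vectorized)."""
    finite = np.isfinite(data)
    n = finite.sum(axis=0)
    filled = np.where(finite, data, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = filled.sum(axis=0) / n
        var = (np.where(finite, (data - mean) ** 2, 0.0).sum(axis=0)
               / np.maximum(n - ddof, 1))
        out = np.sqrt(var) / np.abs(mean)
    out[(n < 2) | (np.abs(mean) < eps)] = np.nan
    return out


def _vector_name(region: str, column: str) -> str:
    # ITH_{seq}_{class}_{feature} / PTH_{Peri*}_{seq}_{class}_{feature}
    if region == "ITH":
        return f"ITH_{column}"
    return f"PTH_{region}_{column}"


def heterogeneity_vector(tables: dict[str, pd.DataFrame]) -> pd.Series:
    """Assemble the 1712-entry case vector from the four per-region tables.

    Parameters
    ----------
    tables : dict
        Region name (``ITH``, ``Peri3``, ``Peri5``, ``Peri7``) -> habitat
        feature table (rows habitats x 428 feature columns).

    Returns
    -------
    pandas.Series
        Named CV values; missing cells stay NaN here (cohort-median
        imputation is a modeling-time, train-split-only operation).
    """
    for region in REGION_ORDER:
        if region not in tables:
            raise ValueError(f"missing region table: {region}")
    names: list[str] = []
    values: list[np.ndarray] = []
    for region in REGION_ORDER:
        table = tables[region]
        names.extend(_vector_name(region, col) for col in table.columns)
        values.append(_cv_columns(table.to_numpy(np.float64)))
    vec = pd.Series(np.concatenate(values), index=names)
    if len(vec) != len(tables["ITH"].columns) * len(REGION_ORDER):
        raise AssertionError("heterogeneity vector length inconsistent with inputs")
    return vec


def icc_2_1(data: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1): two-way random effects, absolute agreement,
    single measurement.

    Parameters
    ----------
    data : ndarray, shape (n_targets, n_raters) or (n_targets, n_raters, n_features)
        Measurements; targets are cases, raters are repeated settings or
        observers.

    Returns
    -------
    float or ndarray
        ICC per feature; NaN where the ANOVA denominators degenerate.
    """
    x = np.asarray(data, np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    n, k, _ = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 targets and >= 2 raters")
    grand = x.mean(axis=(0, 1))
    row_mean = x.mean(axis=1)   # (n, f)
    col_mean = x.mean(axis=0)   # (k, f)
    ssr = k * ((row_mean - grand) ** 2).sum(axis=0)
    ssc = n * ((col_mean - grand) ** 2).sum(axis=0)
    sse = ((x - row_mean[:, None, :] - col_mean[None, :, :] + grand) ** 2).sum(axis=(0, 1))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc = np.where(np.abs(denom) < 1e-300, np.nan, icc)
    return float(icc[0]) if squeeze else icc


def stability_analysis(
    vectors_by_K: dict[int, pd.DataFrame],
    features: list[str] | None = None,
) -> pd.Series:
    """Feature stability across habitat-count settings as ICC(2,1).

    ``vectors_by_K`` maps each habitat count K (e.g. 30, 40, 50, 60, 70) to
    a cases x features heterogeneity matrix computed at that K. The K
    settings act as raters and cases as targets; high ICC means the feature
    is insensitive to the habitat count.
    """
    ks = sorted(vectors_by_K)
    if len(ks) < 2:
        raise ValueError("stability analysis needs >= 2 habitat-count settings")
    first = vectors_by_K[ks[0]]
    if features is None:
        features = list(first.columns)
    if len(first) < 5:
        logger.warning("stability analysis on < 5 cases is unreliable")
    data = np.stack(
        [vectors_by_K[k].loc[first.index, features].to_numpy() for k in ks], axis=1
    )  # (cases, K settings, features)
    # cases with any missing cell are dropped per feature (pairwise)
    iccs = np.full(len(features), np.nan)
    finite = np.isfinite(data).all(axis=1)  # (cases, features)
    for fi in range(len(features)):
        sub = data[finite[:, fi], :, fi]
        if sub.shape[0] >= 2 and np.ptp(sub) > 0:
            iccs[fi] = icc_2_1(sub)
    return pd.Series(iccs, index=features, name="ICC")
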
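"""Standard radiomic feature set: 107 features per (sequence, ROI).

Implements the canonical unfiltered-image feature classes — 18 first-order,
14 shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM features — from
their reference definitions, on 3D ROIs with anisotropic voxel spacing.
Intensities are discretized with a fixed bin width (default 0.1, suited to
z-scored inputs); texture matrices use 13 unique 3D directions at distance 1
and 26-connectivity where zones/dependences are involved.

Features that are undefined on degenerate ROIs (e.g. texture on a one- or
two-voxel habitat) are returned as NaN — recorded as missing, never silently
zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import marching_cubes

from .habitats import HabitatMap
from .io import SEQUENCES, VolumeStack

DEFAULT_BIN_WIDTH = 0.1
MIN_TEXTURE_VOXELS = 3

#: 13 unique (up to sign) neighbour offsets on a 3D grid
OFFSETS_3D = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]
SHAPE_NAMES = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
]
GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]
GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

FEATURE_CLASSES = {
    "firstorder": FIRSTORDER_NAMES,
    "shape": SHAPE_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def feature_manifest() -> list[str]:
    """The 107 canonical ``{class}_{feature}`` names in fixed order."""
    return [f"{cls}_{name}" for cls, names in FEATURE_CLASSES.items() for name in names]


N_FEATURES = len(feature_manifest())  # 107


# ---------------------------------------------------------------------------
# helpers

def _bbox(mask: np.ndarray, pad: int = 1) -> tuple[slice, ...]:
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(i.min()) - pad, 0), min(int(i.max()) + pad + 1, s))
        for i, s in zip(idx, mask.shape)
    )


def discretize(values: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Fixed-bin-width discretization to integer gray levels >= 1.

    Bin edges are aligned to multiples of the bin width, so the level of a
    voxel does not depend on which ROI it is evaluated in.
    """
    v = np.asarray(values, np.float64)
    lo = np.floor(v.min() / bin_width)
    lev = np.floor(v / bin_width) - lo + 1
    return lev.astype(np.int64)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# first order

def firstorder_features(values: np.ndarray, voxel_volume: float,
                        bin_width: float = DEFAULT_BIN_WIDTH) -> dict[str, float]:
    x = np.asarray(values, np.float64)
    n = x.size
    mean = float(x.mean())
    p10, p25, med, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    var = float(x.var())
    robust = x[(x >= p10) & (x <= p90)]
    lev = discretize(x, bin_width)
    hist = np.bincount(lev)[1:]
    p = hist[hist > 0] / n
    if var > 0:
        m = x - mean
        skew = float((m**3).mean() / var**1.5)
        kurt = float((m**4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": voxel_volume * float((x**2).sum()),
        "Entropy": _entropy2(p),
        "Minimum": float(x.min()),
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": med,
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size else np.nan,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# shape

def _max_pairwise(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    if len(pts) > 400:  # reduce via convex hull when large
        try:
            from scipy.spatial import ConvexHull
            pts = pts[ConvexHull(pts, qhull_options="QJ").vertices]
        except Exception:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _max_diameter_plane(coords: np.ndarray, fixed_axis: int) -> float:
    """Max in-plane diameter over slices perpendicular to ``fixed_axis``."""
    best = 0.0
    other = [a for a in range(3) if a != fixed_axis]
    vals = coords[:, fixed_axis]
    for v in np.unique(vals):
        best = max(best, _max_pairwise(coords[vals == v][:, other]))
    return best


def shape_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    mask = np.asarray(mask, bool)
    n = int(mask.sum())
    sp = np.asarray(spacing, np.float64)
    voxel_volume = float(np.prod(sp))
    out = dict.fromkeys(SHAPE_NAMES, np.nan)
    out["VoxelVolume"] = n * voxel_volume
    if n == 0:
        return out

    bb = _bbox(mask)
    sub = np.pad(mask[bb].astype(np.float64), 1)
    try:
        verts, faces, _, _ = marching_cubes(sub, level=0.5, spacing=tuple(sp))
        v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
        mesh_volume = float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)
        surface = float(0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1).sum())
        out["MeshVolume"] = mesh_volume
        out["SurfaceArea"] = surface
        if mesh_volume > 0 and surface > 0:
            out["SurfaceVolumeRatio"] = surface / mesh_volume
            out["Sphericity"] = (36 * np.pi * mesh_volume**2) ** (1 / 3) / surface
        out["Maximum3DDiameter"] = _max_pairwise(verts)
    except Exception:
        pass  # degenerate geometry: mesh features stay missing

    coords = np.column_stack(np.nonzero(mask)).astype(np.float64) * sp
    out["Maximum2DDiameterSlice"] = _max_diameter_plane(coords, 2)
    out["Maximum2DDiameterColumn"] = _max_diameter_plane(coords, 1)
    out["Maximum2DDiameterRow"] = _max_diameter_plane(coords, 0)

    centred = coords - coords.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(np.cov(centred.T, bias=True)))[::-1] if n > 1 else np.zeros(3)
    eig = np.clip(eig, 0, None)
    out["MajorAxisLength"] = 4 * float(np.sqrt(eig[0]))
    out["MinorAxisLength"] = 4 * float(np.sqrt(eig[1]))
    out["LeastAxisLength"] = 4 * float(np.sqrt(eig[2]))
    if eig[0] > 0:
        out["Elongation"] = float(np.sqrt(eig[1] / eig[0]))
        out["Flatness"] = float(np.sqrt(eig[2] / eig[0]))
    return out


# ---------------------------------------------------------------------------
# GLCM

def glcm_features(disc: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """24 co-occurrence features, computed per direction (13 symmetric 3D
    offsets, distance 1) and averaged over directions. Vectorized over the
    direction axis."""
    levels = np.unique(disc[mask])
    ng = len(levels)
    rank = np.zeros(int(levels.max()) + 1, np.int64)
    rank[levels] = np.arange(ng)
    lv = levels.astype(np.float64)

    mats = []
    for off in OFFSETS_3D:
        sl_a = tuple(slice(max(o, 0), s + min(o, 0)) for o, s in zip(off, disc.shape))
        sl_b = tuple(slice(max(-o, 0), s + min(-o, 0)) for o, s in zip(off, disc.shape))
        valid = mask[sl_a] & mask[sl_b]
        if not valid.any():
            continue
        a = rank[disc[sl_a][valid]]
        b = rank[disc[sl_b][valid]]
        mat = np.zeros((ng, ng))
        np.add.at(mat, (a, b), 1.0)
        mat = mat + mat.T  # symmetric
        mats.append(mat / mat.sum())
    if not mats:
        return dict.fromkeys(GLCM_NAMES, np.nan)

    P = np.stack(mats)                      # (A, ng, ng), each normalized
    A = len(mats)
    i = lv[None, :, None]
    j = lv[None, None, :]
    px = P.sum(axis=2)                      # (A, ng); symmetric so py == px
    mu = (px * lv).sum(axis=1)              # (A,)
    sig2 = (px * (lv[None, :] - mu[:, None]) ** 2).sum(axis=1)

    absdiff = np.abs(lv[:, None] - lv[None, :])
    diff_idx = absdiff.astype(np.int64)
    ndiff = int(diff_idx.max()) + 1
    flat_d = (np.arange(A)[:, None, None] * ndiff + diff_idx[None]).ravel()
    pdiff = np.bincount(flat_d, weights=P.ravel(), minlength=A * ndiff).reshape(A, ndiff)
    dvals = np.arange(ndiff, dtype=np.float64)
    da = (pdiff * dvals).sum(axis=1)

    sum_lv = lv[:, None] + lv[None, :]
    smin = int(sum_lv.min())
    sum_idx = (sum_lv - smin).astype(np.int64)
    nsum = int(sum_idx.max()) + 1
    flat_s = (np.arange(A)[:, None, None] * nsum + sum_idx[None]).ravel()
    psum = np.bincount(flat_s, weights=P.ravel(), minlength=A * nsum).reshape(A, nsum)
    svals = np.arange(nsum, dtype=np.float64) + smin

    def ent(p, axis):
        return -(np.where(p > 0, p, 1.0) * np.log2(np.where(p > 0, p, 1.0))).sum(axis=axis)

    hx = ent(px, 1)
    hxy = ent(P, (1, 2))
    outer = px[:, :, None] * px[:, None, :]
    hxy1 = -(np.where(P > 0, P, 0.0) * np.log2(np.clip(outer, 1e-300, None))).sum(axis=(1, 2))
    hxy2 = ent(outer, (1, 2))

    corr = np.where(sig2 > 0,
                    ((P * i * j).sum(axis=(1, 2)) - mu**2) / np.where(sig2 > 0, sig2, 1.0),
                    1.0)
    imc1 = np.where(hx > 0, (hxy - hxy1) / np.where(hx > 0, hx, 1.0), 0.0)
    imc2 = np.where(hxy2 >= hxy, np.sqrt(np.clip(1 - np.exp(-2 * (hxy2 - hxy)), 0, None)), 0.0)

    offdiag = absdiff > 0
    inv_var = (P[:, offdiag] / absdiff[offdiag] ** 2).sum(axis=1) if offdiag.any() \
        else np.zeros(A)

    if ng > 1:
        safe_px = np.where(px > 0, px, 1.0)
        # Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) px(k))
        q = np.einsum("aik,ajk->aij", P / safe_px[:, :, None], P / safe_px[:, None, :])
        eig = np.sort(np.real(np.linalg.eigvals(q)), axis=1)
        mcc = np.sqrt(np.clip(eig[:, -2], 0, None))
    else:
        mcc = np.ones(A)

    dd = sum_lv[None] - 2 * mu[:, None, None]
    per = {
        "Autocorrelation": (P * i * j).sum(axis=(1, 2)),
        "JointAverage": mu,
        "ClusterProminence": (P * dd**4).sum(axis=(1, 2)),
        "ClusterShade": (P * dd**3).sum(axis=(1, 2)),
        "ClusterTendency": (P * dd**2).sum(axis=(1, 2)),
        "Contrast": (P * (i - j) ** 2).sum(axis=(1, 2)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(pdiff, 1),
        "DifferenceVariance": (pdiff * (dvals[None] - da[:, None]) ** 2).sum(axis=1),
        "JointEnergy": (P**2).sum(axis=(1, 2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": (P / (1 + (i - j) ** 2)).sum(axis=(1, 2)),
        "Idmn": (P / (1 + ((i - j) / ng) ** 2)).sum(axis=(1, 2)),
        "Id": (P / (1 + np.abs(i - j))).sum(axis=(1, 2)),
        "Idn": (P / (1 + np.abs(i - j) / ng)).sum(axis=(1, 2)),
        "InverseVariance": inv_var,
        "MaximumProbability": P.max(axis=(1, 2)),
        "SumAverage": (psum * svals).sum(axis=1),
        "SumEntropy": ent(psum, 1),
        "SumSquares": (P * (i - mu[:, None, None]) ** 2).sum(axis=(1, 2)),
        "MCC": mcc,
    }
    return {k: float(np.mean(v)) for k, v in per.items()}


# ---------------------------------------------------------------------------
# GLRLM

def _shift(arr: np.ndarray, off: tuple[int, int, int], fill=0) -> np.ndarray:
    """Array shifted so that ``out[x] = arr[x + off]`` (fill outside grid)."""
    out = np.full_like(arr, fill)
    src = tuple(slice(max(o, 0), s + min(o, 0)) for o, s in zip(off, arr.shape))
    dst = tuple(slice(max(-o, 0), s + min(-o, 0)) for o, s in zip(off, arr.shape))
    out[dst] = arr[src]
    return out


def _runs_along(disc: np.ndarray, mask: np.ndarray, off: tuple[int, int, int]):
    """(levels, run lengths) of maximal same-level runs along one direction.

    A run breaks at ROI boundaries and at level changes. Run lengths are
    propagated backwards from the run tail with repeated shifts, so the scan
    is fully vectorized.
    """
    succ_same = mask & _shift(mask, off) & (disc == _shift(disc, off, fill=-1))
    length = np.ones(disc.shape, np.int64)
    length[~mask] = 0
    while True:
        nxt = np.where(succ_same, 1 + _shift(length, off), length)
        nxt[~mask] = 0
        if (nxt == length).all():
            break
        length = nxt
    neg = tuple(-o for o in off)
    pred_same = mask & _shift(mask, neg) & (disc == _shift(disc, neg, fill=-1))
    start = mask & ~pred_same
    return disc[start].tolist(), length[start].tolist()


def glrlm_features(disc: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """16 run-length features; run matrix accumulated over the 13 directions."""
    n_vox = int(mask.sum())
    levels_all, lengths_all = [], []
    for off in OFFSETS_3D:
        lv, ln = _runs_along(disc, mask, off)
        levels_all += lv
        lengths_all += ln
    if not levels_all:
        return dict.fromkeys(GLRLM_NAMES, np.nan)
    lev = np.asarray(levels_all, np.float64)
    rl = np.asarray(lengths_all, np.float64)
    nr = float(len(lev))

    def nonuni(vals: np.ndarray) -> float:
        _, counts = np.unique(vals, return_counts=True)
        return float((counts.astype(np.float64) ** 2).sum())

    gl_mean = lev.mean()
    rl_mean = rl.mean()
    pair_counts = np.unique(np.column_stack([lev, rl]), axis=0, return_counts=True)[1]
    ent = _entropy2(pair_counts / nr)
    return {
        "ShortRunEmphasis": float((1 / rl**2).mean()),
        "LongRunEmphasis": float((rl**2).mean()),
        "GrayLevelNonUniformity": nonuni(lev) / nr,
        "GrayLevelNonUniformityNormalized": nonuni(lev) / nr**2,
        "RunLengthNonUniformity": nonuni(rl) / nr,
        "RunLengthNonUniformityNormalized": nonuni(rl) / nr**2,
        "RunPercentage": nr / (n_vox * len(OFFSETS_3D)),
        "GrayLevelVariance": float(((lev - gl_mean) ** 2).mean()),
        "RunVariance": float(((rl - rl_mean) ** 2).mean()),
        "RunEntropy": ent,
        "LowGrayLevelRunEmphasis": float((1 / lev**2).mean()),
        "HighGrayLevelRunEmphasis": float((lev**2).mean()),
        "ShortRunLowGrayLevelEmphasis": float((1 / (lev**2 * rl**2)).mean()),
        "ShortRunHighGrayLevelEmphasis": float((lev**2 / rl**2).mean()),
        "LongRunLowGrayLevelEmphasis": float((rl**2 / lev**2).mean()),
        "LongRunHighGrayLevelEmphasis": float((lev**2 * rl**2).mean()),
    }


# ---------------------------------------------------------------------------
# GLSZM

def glszm_features(disc: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """16 size-zone features; zones are 26-connected same-level components."""
    n_vox = int(mask.sum())
    struct = ndimage.generate_binary_structure(3, 3)
    levels, sizes = [], []
    for l in np.unique(disc[mask]):
        sel = (disc == l) & mask
        lab, nlab = ndimage.label(sel[_bbox(sel, pad=0)], structure=struct)
        if nlab:
            cnt = np.bincount(lab.ravel())[1:]
            levels += [float(l)] * nlab
            sizes += cnt.tolist()
    if not levels:
        return dict.fromkeys(GLSZM_NAMES, np.nan)
    lev = np.asarray(levels, np.float64)
    sz = np.asarray(sizes, np.float64)
    nz = float(len(lev))

    def nonuni(vals: np.ndarray) -> float:
        _, counts = np.unique(vals, return_counts=True)
        return float((counts.astype(np.float64) ** 2).sum())

    pair_counts = np.unique(np.column_stack([lev, sz]), axis=0, return_counts=True)[1]
    return {
        "SmallAreaEmphasis": float((1 / sz**2).mean()),
        "LargeAreaEmphasis": float((sz**2).mean()),
        "GrayLevelNonUniformity": nonuni(lev) / nz,
        "GrayLevelNonUniformityNormalized": nonuni(lev) / nz**2,
        "SizeZoneNonUniformity": nonuni(sz) / nz,
        "SizeZoneNonUniformityNormalized": nonuni(sz) / nz**2,
        "ZonePercentage": nz / n_vox,
        "GrayLevelVariance": float(((lev - lev.mean()) ** 2).mean()),
        "ZoneVariance": float(((sz - sz.mean()) ** 2).mean()),
        "ZoneEntropy": _entropy2(pair_counts / nz),
        "LowGrayLevelZoneEmphasis": float((1 / lev**2).mean()),
        "HighGrayLevelZoneEmphasis": float((lev**2).mean()),
        "SmallAreaLowGrayLevelEmphasis": float((1 / (lev**2 * sz**2)).mean()),
        "SmallAreaHighGrayLevelEmphasis": float((lev**2 / sz**2).mean()),
        "LargeAreaLowGrayLevelEmphasis": float((sz**2 / lev**2).mean()),
        "LargeAreaHighGrayLevelEmphasis": float((lev**2 * sz**2).mean()),
    }


# ---------------------------------------------------------------------------
# GLDM / NGTDM share a neighbour scan

def _neighbour_stats(disc: np.ndarray, mask: np.ndarray):
    """Neighbour count, same-level neighbour count and level-sum per voxel."""
    cnt = np.zeros(disc.shape)
    eq = np.zeros(disc.shape)
    lsum = np.zeros(disc.shape)
    for off in OFFSETS_3D:
        for sgn in (1, -1):
            o = tuple(int(sgn * x) for x in off)
            sl_a = tuple(slice(max(x, 0), s + min(x, 0)) for x, s in zip(o, disc.shape))
            sl_b = tuple(slice(max(-x, 0), s + min(-x, 0)) for x, s in zip(o, disc.shape))
            valid = mask[sl_a] & mask[sl_b]
            add = np.zeros_like(cnt[sl_a])
            add[valid] = 1
            cnt[sl_a] += add
            same = np.zeros_like(add)
            same[valid & (disc[sl_a] == disc[sl_b])] = 1
            eq[sl_a] += same
            ls = np.zeros_like(add)
            ls[valid] = disc[sl_b][valid]
            lsum[sl_a] += ls
    return cnt, eq, lsum


def gldm_features(disc: np.ndarray, mask: np.ndarray, stats=None) -> dict[str, float]:
    """14 dependence features (alpha = 0: a neighbour is dependent when it has
    the same discretized level); dependence size = same-level neighbours + 1."""
    _, eq, _ = stats if stats is not None else _neighbour_stats(disc, mask)
    lev = disc[mask].astype(np.float64)
    dep = eq[mask] + 1.0
    nz = float(lev.size)

    def nonuni(vals: np.ndarray) -> float:
        _, counts = np.unique(vals, return_counts=True)
        return float((counts.astype(np.float64) ** 2).sum())

    pair_counts = np.unique(np.column_stack([lev, dep]), axis=0, return_counts=True)[1]
    return {
        "SmallDependenceEmphasis": float((1 / dep**2).mean()),
        "LargeDependenceEmphasis": float((dep**2).mean()),
        "GrayLevelNonUniformity": nonuni(lev) / nz,
        "DependenceNonUniformity": nonuni(dep) / nz,
        "DependenceNonUniformityNormalized": nonuni(dep) / nz**2,
        "GrayLevelVariance": float(((lev - lev.mean()) ** 2).mean()),
        "DependenceVariance": float(((dep - dep.mean()) ** 2).mean()),
        "DependenceEntropy": _entropy2(pair_counts / nz),
        "LowGrayLevelEmphasis": float((1 / lev**2).mean()),
        "HighGrayLevelEmphasis": float((lev**2).mean()),
        "SmallDependenceLowGrayLevelEmphasis": float((1 / (lev**2 * dep**2)).mean()),
        "SmallDependenceHighGrayLevelEmphasis": float((lev**2 / dep**2).mean()),
        "LargeDependenceLowGrayLevelEmphasis": float((dep**2 / lev**2).mean()),
        "LargeDependenceHighGrayLevelEmphasis": float((lev**2 * dep**2).mean()),
    }


def ngtdm_features(disc: np.ndarray, mask: np.ndarray, stats=None) -> dict[str, float]:
    """5 neighbourhood gray-tone difference features."""
    cnt, _, lsum = stats if stats is not None else _neighbour_stats(disc, mask)
    has_nb = mask & (cnt > 0)
    lev_vox = disc[has_nb].astype(np.float64)
    nb_mean = lsum[has_nb] / cnt[has_nb]
    nvp = float(lev_vox.size)
    if nvp == 0:
        return dict.fromkeys(NGTDM_NAMES, np.nan)

    levels = np.unique(lev_vox).astype(np.float64)
    p_i = np.array([(lev_vox == l).sum() for l in levels]) / nvp
    s_i = np.array([np.abs(lev_vox[lev_vox == l] - nb_mean[lev_vox == l]).sum() for l in levels])
    ngp = len(levels)

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    li = levels[:, None]
    lj = levels[None, :]
    pi = p_i[:, None]
    pj = p_i[None, :]
    contrast = 0.0
    if ngp > 1:
        contrast = float((pi * pj * (li - lj) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nvp)
    busy_den = float(np.abs(li * pi - lj * pj).sum())
    busyness = coarse_den / busy_den if busy_den > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        comp = np.abs(li - lj) * (pi * s_i[:, None] + pj * s_i[None, :]) / (pi + pj)
    complexity = float(np.nansum(comp) / nvp)
    s_sum = float(s_i.sum())
    strength = float(((pi + pj) * (li - lj) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# public extraction API

def extract_features(
    volume: np.ndarray,
    roi: np.ndarray,
    spacing: tuple[float, float, float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    shape_cache: dict[str, float] | None = None,
    classes: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Compute the 107-feature set for one sequence over one ROI.

    Returns ``{class}_{feature}`` -> value, NaN where undefined. Texture
    classes require at least ``MIN_TEXTURE_VOXELS`` voxels; below that they
    are recorded missing. ``shape_cache`` allows reusing the (sequence-
    independent) shape features across sequences; ``classes`` restricts the
    computed feature classes (the default is all seven).
    """
    roi = np.asarray(roi, bool)
    n = int(roi.sum())
    if n < 1:
        raise ValueError("ROI must contain at least one voxel")
    if volume.shape != roi.shape:
        raise ValueError("volume and ROI shapes differ")
    wanted = set(classes) if classes is not None else set(FEATURE_CLASSES)

    voxel_volume = float(np.prod(spacing))
    out: dict[str, float] = {}

    if "firstorder" in wanted:
        fo = firstorder_features(volume[roi], voxel_volume, bin_width)
        out.update({f"firstorder_{k}": v for k, v in fo.items()})

    if "shape" in wanted:
        shp = shape_cache if shape_cache is not None else shape_features(roi, spacing)
        out.update({f"shape_{k}": v for k, v in shp.items()})

    texture = [c for c in ("glcm", "glrlm", "glszm", "gldm", "ngtdm") if c in wanted]
    if texture and n >= MIN_TEXTURE_VOXELS:
        bb = _bbox(roi)
        sub_mask = roi[bb]
        disc = np.zeros(sub_mask.shape, np.int64)
        disc[sub_mask] = discretize(volume[bb][sub_mask], bin_width)
        nstats = _neighbour_stats(disc, sub_mask) \
            if ("gldm" in wanted or "ngtdm" in wanted) else None
        calls = {
            "glcm": lambda: glcm_features(disc, sub_mask),
            "glrlm": lambda: glrlm_features(disc, sub_mask),
            "glszm": lambda: glszm_features(disc, sub_mask),
            "gldm": lambda: gldm_features(disc, sub_mask, stats=nstats),
            "ngtdm": lambda: ngtdm_features(disc, sub_mask, stats=nstats),
        }
        for cls in texture:
            out.update({f"{cls}_{k}": v for k, v in calls[cls]().items()})
    else:
        for cls in texture:
            for name in FEATURE_CLASSES[cls]:
                out[f"{cls}_{name}"] = np.nan
    return out


def extract_all_sequences(
    stack: VolumeStack,
    roi: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    classes: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """428 named values: 107 features x 4 sequences, shape shared."""
    wanted = set(classes) if classes is not None else set(FEATURE_CLASSES)
    shp = shape_features(roi, stack.spacing) if "shape" in wanted else None
    out: dict[str, float] = {}
    for seq in SEQUENCES:
        feats = extract_features(stack.volumes[seq], roi, stack.spacing,
                                 bin_width, shape_cache=shp, classes=classes)
        out.update({f"{seq}_{k}": v for k, v in feats.items()})
    return out


def extract_per_habitat(
    stack: VolumeStack,
    habitat_map: HabitatMap,
    bin_width: float = DEFAULT_BIN_WIDTH,
    classes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-habitat feature table: ``K_eff`` rows x 428 columns."""
    rows = []
    for h in range(1, habitat_map.K_eff + 1):
        rows.append(extract_all_sequences(stack, habitat_map.habitat_mask(h),
                                          bin_width, classes=classes))
    df = pd.DataFrame(rows, index=pd.RangeIndex(1, habitat_map.K_eff + 1, name="habitat"))
    df.attrs["region_name"] = habitat_map.region_name
    return df


def extract_whole_region(
    stack: VolumeStack,
    roi: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    classes: tuple[str, ...] | None = None,
) -> pd.Series:
    """428 named values over the full region (no habitat segmentation)."""
    return pd.Series(extract_all_sequences(stack, roi, bin_width, classes=classes))
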
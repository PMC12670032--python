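"""Habitat encoding: masked SLIC supervoxels with an exact-count guarantee.

Each region (tumor or peritumoral band) is partitioned into K habitats by
simple linear iterative clustering on the four normalized sequence channels,
with the spatial term scaled by physical voxel spacing. Because SLIC does not
guarantee the requested number of clusters, a deterministic post-pass merges
the smallest habitat into its most similar neighbour (or splits the largest
along its principal axis) until exactly ``K_eff = min(K, n_voxels)`` nonempty
habitats remain — the fixed count the downstream coefficient-of-variation
bookkeeping relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import slic

from .io import SEQUENCES, VolumeStack

logger = logging.getLogger(__name__)

DEFAULT_K = 50
DEFAULT_COMPACTNESS = 0.1
DEFAULT_SEED = 20406


@dataclass
class HabitatMap:
    """Integer habitat label field over one region.

    ``labels`` is 0 outside the region and ``1..K_eff`` inside; every habitat
    id in that range is nonempty.
    """

    labels: np.ndarray
    region_name: str
    K_requested: int
    K_eff: int

    def habitat_mask(self, h: int) -> np.ndarray:
        return self.labels == h

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.K_eff + 1)[1:]


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Relabel to consecutive ids 1..n ordered by first (flat) occurrence."""
    flat = labels.ravel()
    inside = flat > 0
    ids, first = np.unique(flat[inside], return_index=True)
    order = ids[np.argsort(first)]
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    lut[order] = np.arange(1, len(order) + 1)
    out = np.zeros_like(labels, dtype=np.int32)
    out.ravel()[inside] = lut[flat[inside]]
    return out


def _split_components(labels: np.ndarray) -> np.ndarray:
    """Split spatially disconnected habitats into separate labels."""
    struct = ndimage.generate_binary_structure(3, 3)
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for h in np.unique(labels[labels > 0]):
        comp, ncomp = ndimage.label(labels == h, structure=struct)
        for c in range(1, ncomp + 1):
            out[comp == c] = nxt
            nxt += 1
    return out


def _adjacency(labels: np.ndarray) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for ax in range(labels.ndim):
        a = np.moveaxis(labels, ax, 0)[:-1]
        b = np.moveaxis(labels, ax, 0)[1:]
        touch = (a > 0) & (b > 0) & (a != b)
        for x, y in zip(a[touch].ravel(), b[touch].ravel()):
            adj.setdefault(int(x), set()).add(int(y))
            adj.setdefault(int(y), set()).add(int(x))
    return adj


def _merge_once(labels: np.ndarray, feats: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Merge the smallest habitat into its most similar neighbour."""
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    order = np.lexsort((ids, counts))
    smallest = int(ids[order[0]])
    adj = _adjacency(labels)
    candidates = sorted(adj.get(smallest, set()))
    if not candidates:
        candidates = [int(i) for i in ids if i != smallest]
    mean_s = feats[labels[region] == smallest].mean(axis=0)
    best, best_d = candidates[0], np.inf
    for c in candidates:
        d = float(np.linalg.norm(feats[labels[region] == c].mean(axis=0) - mean_s))
        if d < best_d:
            best, best_d = c, d
    labels = labels.copy()
    labels[labels == smallest] = best
    return labels


def _split_once(labels: np.ndarray, coords_mm: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Bisect the largest habitat along its principal spatial axis."""
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    order = np.lexsort((ids, -counts))
    largest = int(ids[order[0]])
    sel = labels[region] == largest
    pts = coords_mm[sel]
    centred = pts - pts.mean(axis=0)
    # principal axis; fall back to voxel order when geometry is degenerate
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt[0]
    cut = np.median(proj)
    half = proj > cut
    if not half.any() or half.all():
        half = np.zeros(len(proj), bool)
        half[: len(proj) // 2] = True
    new_id = int(labels.max()) + 1
    labels = labels.copy()
    region_idx = np.flatnonzero(region.ravel())
    flat = labels.ravel()
    target = region_idx[sel]
    flat[target[half]] = new_id
    return labels


def encode_habitats(
    stack: VolumeStack,
    region: np.ndarray,
    K: int = DEFAULT_K,
    compactness: float = DEFAULT_COMPACTNESS,
    seed: int = DEFAULT_SEED,
    region_name: str = "ITH",
    max_iter: int | None = None,
) -> HabitatMap:
    """Partition a region into exactly ``min(K, n_voxels)`` habitats.

    Parameters
    ----------
    stack : VolumeStack
        Normalized multi-sequence stack; the four channels enter SLIC with
        equal weight.
    region : ndarray of bool
        Region mask (tumor or peritumoral band).
    K : int
        Requested habitat count (default 50).
    compactness : float
        SLIC compactness on z-scored channels.
    seed : int
        Kept for the determinism contract; the procedure is deterministic.

    Returns
    -------
    HabitatMap
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    region = np.asarray(region, bool)
    n_vox = int(region.sum())
    if n_vox < 1:
        raise ValueError("region must contain at least one voxel")
    K_eff = min(K, n_vox)

    if K_eff == n_vox:
        labels = np.zeros(region.shape, dtype=np.int32)
        labels[region] = np.arange(1, n_vox + 1)
        return HabitatMap(labels, region_name, K, K_eff)

    channels = np.stack([np.asarray(stack.volumes[s], np.float64) for s in SEQUENCES], axis=-1)
    labels = slic(
        channels,
        n_segments=K_eff,
        compactness=compactness,
        mask=region,
        spacing=stack.spacing,
        channel_axis=-1,
        start_label=1,
        enforce_connectivity=True,
    ).astype(np.int32)
    labels[~region] = 0
    if not (labels > 0).any():  # SLIC degenerated (e.g. K == 1 on a mask)
        labels[region] = 1
    labels = _split_components(labels)

    feats = channels[region]
    ii, jj, kk = np.nonzero(region)
    coords_mm = np.column_stack([ii, jj, kk]).astype(np.float64) * np.asarray(stack.spacing)

    budget = max_iter if max_iter is not None else 4 * n_vox + 100
    steps = 0
    while True:
        count = len(np.unique(labels[labels > 0]))
        if count == K_eff:
            break
        if steps >= budget:
            raise RuntimeError(
                f"habitat count enforcement did not converge: have {count}, want {K_eff}"
            )
        if count > K_eff:
            labels = _merge_once(labels, feats, region)
        else:
            labels = _split_once(labels, coords_mm, region)
        steps += 1

    labels = _relabel_consecutive(labels)
    hm = HabitatMap(labels, region_name, K, K_eff)
    assert (hm.labels > 0).sum() == n_vox and hm.sizes().min() >= 1
    return hm
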
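"""Peritumoral band masks by anisotropic physical-distance dilation.

A band at distance d is the set of voxels outside the tumor whose Euclidean
distance (in mm, honouring anisotropic voxel spacing) to the tumor surface is
at most d. Bands are cumulative shells: Peri3 is contained in Peri5 is
contained in Peri7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

DEFAULT_DISTANCES = (3.0, 5.0, 7.0)


@dataclass
class RegionMaskSet:
    """Tumor mask plus nested peritumoral band masks on one grid."""

    tumor: np.ndarray
    bands: dict[str, np.ndarray]
    distances_mm: tuple[float, ...]

    def regions(self) -> dict[str, np.ndarray]:
        """All analysis regions keyed by name (``ITH`` = intratumoral)."""
        return {"ITH": self.tumor, **self.bands}


def band_name(d: float) -> str:
    return f"Peri{int(d) if float(d).is_integer() else d}"


def make_peritumoral_bands(
    tumor: np.ndarray,
    spacing: tuple[float, float, float],
    distances: tuple[float, ...] = DEFAULT_DISTANCES,
) -> RegionMaskSet:
    """Build cumulative peritumoral bands at the given distances (mm).

    The band at distance d is ``dilate(tumor, d) \\ tumor`` where dilation is
    the exact Euclidean distance transform of the tumor complement with
    per-axis sampling equal to the voxel spacing, thresholded at d. Bands are
    clipped at the image bounds; a tumor touching the border is allowed but
    logged, an empty band raises.
    """
    tumor = np.asarray(tumor, bool)
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be strictly positive")
    distances = tuple(float(d) for d in distances)
    if any(d < 0 for d in distances) or list(distances) != sorted(distances):
        raise ValueError("distances must be non-negative and increasing")

    border = np.zeros_like(tumor)
    for ax in range(tumor.ndim):
        sl = [slice(None)] * tumor.ndim
        for edge in (0, -1):
            sl[ax] = edge
            border[tuple(sl)] = True
    if (tumor & border).any():
        logger.warning("tumor touches the image border; bands will be clipped")

    # distance from every voxel to the nearest tumor voxel, in mm
    dist = ndimage.distance_transform_edt(~tumor, sampling=spacing)

    bands: dict[str, np.ndarray] = {}
    for d in distances:
        band = (dist <= d) & ~tumor
        if d > 0 and not band.any():
            raise ValueError(f"band at {d} mm is empty after clipping")
        bands[band_name(d)] = band
    return RegionMaskSet(tumor=tumor, bands=bands, distances_mm=distances)
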
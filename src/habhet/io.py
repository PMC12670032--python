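"""NIfTI input/output, grid resampling and per-sequence intensity normalization.

All four MRI sequences of a case (T2-weighted ``T2``, precontrast T1 ``PRE``,
arterial phase ``AP``, hepatobiliary phase ``HBP``) are assumed co-registered;
they are resampled to a common reference grid of 1.0 x 1.0 x 3.0 mm voxels and
z-scored per sequence so that downstream habitat clustering and feature
discretization see comparable intensity scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

SEQUENCES = ("T2", "PRE", "AP", "HBP")
TARGET_SPACING = (1.0, 1.0, 3.0)

#: header jitter tolerated between co-registered sequences (mm / direction cosine)
AFFINE_TOL = 1e-3


@dataclass
class VolumeStack:
    """Four co-registered 3D intensity volumes on a shared grid.

    Parameters
    ----------
    case_id : str
        Case identifier.
    volumes : dict
        Maps sequence name (``T2``, ``PRE``, ``AP``, ``HBP``) to a 3D float
        array. All arrays share one shape.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm, strictly positive.
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine (applies to every sequence).
    """

    case_id: str
    volumes: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) > 1:
            raise ValueError(f"sequences disagree on array shape: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.volumes.values())).shape

    def map(self, fn) -> "VolumeStack":
        """Apply ``fn(volume)`` to every sequence, keeping grid metadata."""
        return VolumeStack(
            self.case_id,
            {k: fn(v) for k, v in self.volumes.items()},
            self.spacing,
            self.affine,
        )


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def _check_congruent(name: str, affine: np.ndarray, ref: np.ndarray) -> None:
    if not np.allclose(affine, ref, atol=AFFINE_TOL):
        raise ValueError(
            f"sequence {name!r}: affine differs from reference beyond "
            f"tolerance {AFFINE_TOL}"
        )


def load_case(
    paths: Mapping[str, str | Path],
    mask_path: str | Path,
    case_id: str = "case",
    target_spacing: tuple[float, float, float] | None = TARGET_SPACING,
) -> tuple[VolumeStack, np.ndarray]:
    """Load the four sequences plus the tumor mask and resample to the grid.

    Parameters
    ----------
    paths : mapping
        Sequence name -> NIfTI path; must contain exactly the keys
        ``T2, PRE, AP, HBP``.
    mask_path : path
        Binary tumor mask on the same grid as the images.
    target_spacing : tuple or None
        Reference voxel size in mm; ``None`` skips resampling.

    Returns
    -------
    (VolumeStack, ndarray of bool)
        Stack and mask on the common grid.
    """
    missing = [s for s in SEQUENCES if s not in paths]
    if missing:
        raise ValueError(f"missing sequence(s): {', '.join(missing)}")

    volumes: dict[str, np.ndarray] = {}
    ref_affine = None
    for seq in SEQUENCES:
        img = nib.load(str(paths[seq]))
        if ref_affine is None:
            ref_affine = img.affine
        else:
            _check_congruent(seq, img.affine, ref_affine)
        volumes[seq] = np.asarray(img.get_fdata(), dtype=np.float64)

    mask_img = nib.load(str(mask_path))
    _check_congruent("mask", mask_img.affine, ref_affine)
    mask = np.asarray(mask_img.get_fdata()) > 0.5
    if not mask.any():
        raise ValueError("empty mask: tumor mask has zero foreground voxels")

    spacing = _spacing_from_affine(ref_affine)
    logger.info("case %s: original spacing %s", case_id, spacing)
    stack = VolumeStack(case_id, volumes, spacing, np.asarray(ref_affine))

    if target_spacing is not None and not np.allclose(spacing, target_spacing):
        stack = resample_stack(stack, target_spacing)
        mask = resample(mask.astype(np.float64), spacing, target_spacing,
                        interpolation="nearest") > 0.5
        if not mask.any():
            raise ValueError("empty mask after resampling")
    return stack, mask


def resample(
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    target_spacing: tuple[float, float, float] = TARGET_SPACING,
    interpolation: str = "linear",
) -> np.ndarray:
    """Resample a 3D array from ``spacing`` to ``target_spacing`` (mm).

    Output shape is ``round(shape * spacing / target)`` per axis, which keeps
    the physical extent within one voxel. ``linear`` is meant for intensity
    images, ``nearest`` for label/mask volumes (value set preserved).
    """
    if any(s <= 0 for s in spacing) or any(s <= 0 for s in target_spacing):
        raise ValueError("voxel spacings must be strictly positive")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    zoom = np.asarray(spacing, float) / np.asarray(target_spacing, float)
    if np.allclose(zoom, 1.0):
        return volume.copy()
    order = 1 if interpolation == "linear" else 0
    return ndimage.zoom(np.asarray(volume, np.float64), zoom, order=order,
                        mode="nearest", grid_mode=True)


def resample_stack(
    stack: VolumeStack,
    target_spacing: tuple[float, float, float] = TARGET_SPACING,
) -> VolumeStack:
    """Resample every sequence of a stack to the target grid (linear)."""
    out = {k: resample(v, stack.spacing, target_spacing) for k, v in stack.volumes.items()}
    affine = stack.affine.copy()
    for i in range(3):
        col = affine[:3, i]
        n = np.linalg.norm(col)
        if n > 0:
            affine[:3, i] = col / n * target_spacing[i]
    return VolumeStack(stack.case_id, out, tuple(target_spacing), affine)


def normalize(volume: np.ndarray, mask_scope: np.ndarray | None = None) -> np.ndarray:
    """Z-score a volume over a scope (whole volume by default).

    The returned array has mean 0 and unit standard deviation over the scope;
    voxels outside the scope are transformed with the same affine map. Raises
    on a constant scope, where the z-score is undefined.
    """
    vol = np.asarray(volume, np.float64)
    scope = vol[mask_scope] if mask_scope is not None else vol
    if scope.size < 2:
        raise ValueError("normalization scope needs at least 2 voxels")
    mu = float(scope.mean())
    sd = float(scope.std(ddof=1))
    if sd == 0:
        raise ValueError("constant volume: zero variance in normalization scope")
    return (vol - mu) / sd


def normalize_stack(stack: VolumeStack, mask_scope: np.ndarray | None = None) -> VolumeStack:
    """Per-sequence z-score normalization of a stack."""
    return stack.map(lambda v: normalize(v, mask_scope))


# ---------------------------------------------------------------------------
# case manifests and writing

def save_case(
    stack: VolumeStack,
    masks: Mapping[str, np.ndarray],
    out_dir: str | Path,
) -> dict:
    """Write a case as NIfTI files plus a manifest entry dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entry: dict = {"case_id": stack.case_id, "sequences": {}, "masks": {}}
    for seq, vol in stack.volumes.items():
        p = out_dir / f"{stack.case_id}_{seq}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), stack.affine), str(p))
        entry["sequences"][seq] = str(p)
    for name, m in masks.items():
        p = out_dir / f"{stack.case_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(m, np.uint8), stack.affine), str(p))
        entry["masks"][name] = str(p)
    return entry


def write_manifest(entries: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"cases": entries}, fh, sort_keys=False)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data["cases"]
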
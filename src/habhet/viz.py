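"""Visualization helpers: habitat overlays on anatomical slices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .habitats import HabitatMap
from .io import VolumeStack


def save_habitat_overlay(
    stack: VolumeStack,
    habitat_map: HabitatMap,
    path: str | Path,
    sequence: str = "AP",
    slice_index: int | None = None,
) -> Path:
    """Write a PNG of one axial slice with the habitat labels overlaid.

    ``slice_index`` defaults to the slice holding the most region voxels.
    """
    labels = habitat_map.labels
    if slice_index is None:
        slice_index = int(np.argmax((labels > 0).sum(axis=(0, 1))))
    img = stack.volumes[sequence][:, :, slice_index]
    lab = labels[:, :, slice_index]

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img.T, cmap="gray", origin="lower")
    masked = np.ma.masked_where(lab.T == 0, lab.T)
    ax.imshow(masked, cmap="tab20", origin="lower", alpha=0.6,
              interpolation="nearest")
    ax.set_title(f"{habitat_map.region_name}: {habitat_map.K_eff} habitats "
                 f"({sequence}, slice {slice_index})")
    ax.axis("off")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
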
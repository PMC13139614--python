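"""Orthogonal-slice PNG export for time-lapse montages.

Stands in for volume-rendered movies: each timepoint is summarized by the
three central orthogonal cut planes through the spheroid centroid, after
translating the spheroid to the image center.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage

__all__ = ["recenter_volume", "save_orthogonal_slices"]


def recenter_volume(volume: np.ndarray, centroid: tuple[float, float, float]) -> np.ndarray:
    """Translate a 3-D volume so ``centroid`` lands on the grid center.

    Integer-voxel shift with zero fill; used to stabilize time-lapse
    exports against spheroid drift.
    """
    center = (np.asarray(volume.shape) - 1) / 2.0
    shift = np.round(center - np.asarray(centroid)).astype(int)
    return ndimage.shift(volume, shift, order=0, cval=0.0)


def save_orthogonal_slices(
    volume: np.ndarray,
    path,
    title: str = "",
    centroid: tuple[float, float, float] | None = None,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
) -> Path:
    """Write central z/y/x cut planes of a 3-D volume to one PNG."""
    vol = volume if centroid is None else recenter_volume(volume, centroid)
    cz, cy, cx = (s // 2 for s in vol.shape)
    planes = [vol[cz], vol[:, cy], vol[:, :, cx]]
    names = ["xy (z center)", "xz (y center)", "yz (x center)"]
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    for ax, plane, name in zip(axes, planes, names):
        im = ax.imshow(plane, cmap=cmap, vmin=vmin, vmax=vmax, origin="lower")
        ax.set_title(name, fontsize=8)
        ax.axis("off")
    fig.colorbar(im, ax=axes, shrink=0.8)
    if title:
        fig.suptitle(title, fontsize=10)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
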
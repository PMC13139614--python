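"""Automatic 3-D spheroid segmentation from the LIV x intensity product.

The well-plate surface under a spheroid is bright but static: it has high
OCT intensity and near-zero LIV.  Multiplying the (rebased, non-negative)
time-averaged dB intensity by the LIV map therefore suppresses the plate
while keeping the dynamic, backscattering spheroid tissue, so a plain
histogram threshold on the product separates spheroid from everything else.

Procedure: Gaussian blur -> Otsu threshold -> binary erosion (ball
structuring element) -> 26-connectivity component labeling, followed by
hole filling, small-object removal, and selection of the spheroid component
(largest; ties broken by mean product).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball, remove_small_objects

from .doct_metrics import IntensitySequence, LIVMap

__all__ = [
    "ProductVolume",
    "SegmentationMask",
    "SegmentationParams",
    "DegenerateInputError",
    "EmptySegmentationError",
    "product_image",
    "otsu_threshold",
    "eroded_otsu_labels",
    "refine_mask",
    "segment_spheroid",
    "dice_coefficient",
]


class DegenerateInputError(ValueError):
    """Raised when a threshold cannot be defined (constant input)."""


class EmptySegmentationError(RuntimeError):
    """Raised when no component survives mask refinement."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the eroded-Otsu procedure (voxel units)."""

    blur_sigma: float = 2.0
    erosion_radius: int = 1
    min_size: int = 100
    n_bins: int = 256
    fill_holes: bool = True
    db_floor_db: float = -30.0  # dB value of the linear log-floor

    def __post_init__(self) -> None:
        if self.blur_sigma < 0 or self.erosion_radius < 0:
            raise ValueError("blur_sigma and erosion_radius must be >= 0")
        if self.min_size < 0 or self.n_bins < 2:
            raise ValueError("min_size must be >= 0 and n_bins >= 2")


@dataclass
class ProductVolume:
    """LIV x rebased-intensity salience volume (>= 0 everywhere)."""

    values: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("product values must be finite and >= 0")


@dataclass
class SegmentationMask:
    """Final boolean spheroid mask plus component provenance."""

    mask: np.ndarray
    component_label: int
    component_table: pd.DataFrame
    params: SegmentationParams


def product_image(
    liv: LIVMap | np.ndarray,
    seq: IntensitySequence,
    db_floor_db: float = -30.0,
) -> ProductVolume:
    """Per-voxel product ``LIV * max(mean_t I_dB - floor_dB, 0)``.

    The time-averaged dB intensity is rebased to a non-negative scale before
    the product so that dim voxels cannot flip the product's sign.
    """
    liv_values = liv.values if isinstance(liv, LIVMap) else np.asarray(liv)
    if liv_values.shape != seq.grid_shape:
        raise ValueError(
            f"LIV shape {liv_values.shape} does not match sequence grid {seq.grid_shape}"
        )
    rebased = np.maximum(seq.mean_db() - db_floor_db, 0.0)
    return ProductVolume(values=liv_values * rebased, voxel_size_um=seq.voxel_size_um)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    Raises :class:`DegenerateInputError` when the input is constant.
    """
    v = np.asarray(values).ravel()
    if v.size == 0 or np.min(v) == np.max(v):
        raise DegenerateInputError("Otsu threshold undefined for constant input")
    return float(threshold_otsu(v, nbins=n_bins))


def eroded_otsu_labels(
    product: ProductVolume | np.ndarray,
    blur_sigma: float = 2.0,
    erosion_radius: int = 1,
    n_bins: int = 256,
) -> np.ndarray:
    """Blur -> Otsu -> binary erosion -> 26-connectivity labeling.

    Returns an integer label volume with 0 = background.
    """
    values = product.values if isinstance(product, ProductVolume) else np.asarray(product)
    if blur_sigma < 0 or erosion_radius < 0:
        raise ValueError("blur_sigma and erosion_radius must be >= 0")
    blurred = ndimage.gaussian_filter(values, sigma=blur_sigma) if blur_sigma > 0 else values
    thr = otsu_threshold(blurred, n_bins=n_bins)
    binary = blurred > thr
    if erosion_radius > 0:
        binary = ndimage.binary_erosion(binary, structure=ball(erosion_radius))
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    return labels


def refine_mask(
    labels: np.ndarray,
    min_size: int = 100,
    fill_holes: bool = True,
    product: np.ndarray | None = None,
    select_label: int | None = None,
    params: SegmentationParams | None = None,
) -> SegmentationMask:
    """Fill cavities, drop specks, and select the spheroid component.

    The spheroid is the largest surviving component by voxel count; ties are
    broken by the highest mean product value (when ``product`` is given).
    ``select_label`` overrides the automatic pick (manual floater removal).
    """
    binary = labels > 0
    if fill_holes:
        binary = ndimage.binary_fill_holes(binary)
    if min_size > 1:
        # max_size semantics: removes components <= max_size, i.e. < min_size
        binary = remove_small_objects(binary, max_size=min_size - 1)
    relabeled, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise EmptySegmentationError("no connected component survived refinement")
    sizes = ndimage.sum_labels(np.ones_like(relabeled), relabeled, index=range(1, n + 1))
    means = (
        ndimage.mean(product, relabeled, index=range(1, n + 1))
        if product is not None
        else np.zeros(n)
    )
    table = pd.DataFrame(
        {"label": np.arange(1, n + 1), "size_voxels": sizes.astype(int), "mean_product": means}
    )
    if select_label is not None:
        if select_label not in table["label"].values:
            raise KeyError(f"label {select_label} not present (have {list(table['label'])})")
        chosen = int(select_label)
    else:
        order = table.sort_values(
            ["size_voxels", "mean_product"], ascending=False, kind="stable"
        )
        chosen = int(order.iloc[0]["label"])
    return SegmentationMask(
        mask=relabeled == chosen,
        component_label=chosen,
        component_table=table,
        params=params or SegmentationParams(),
    )


def segment_spheroid(
    liv: LIVMap,
    seq: IntensitySequence,
    params: SegmentationParams | None = None,
    select_label: int | None = None,
) -> SegmentationMask:
    """Full pipeline: product image -> eroded-Otsu labels -> refined mask."""
    p = params or SegmentationParams()
    prod = product_image(liv, seq, db_floor_db=p.db_floor_db)
    labels = eroded_otsu_labels(
        prod, blur_sigma=p.blur_sigma, erosion_radius=p.erosion_radius, n_bins=p.n_bins
    )
    return refine_mask(
        labels,
        min_size=p.min_size,
        fill_holes=p.fill_holes,
        product=prod.values,
        select_label=select_label,
        params=p,
    )


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)`` of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
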
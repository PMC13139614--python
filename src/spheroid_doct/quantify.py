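"""Per-timepoint scalar readouts inside the segmented spheroid.

For each sample and timepoint the pipeline reports: spheroid volume, mean
LIV, mean OCDS_l, and the two low-dynamics volumes (LDV) — the tissue volume
whose LIV (respectively OCDS_l) falls below an empirical cut-off, read as
non-viable tissue.  Default cut-offs: 3 dB² for LIV, 2e-4 ms⁻¹ for OCDS_l.

Conventions: "below the cut-off" is a strict inequality (ties count as not
low).  Voxels whose OCDS_l is undefined (zero temporal variance, i.e. a
perfectly static signal) are excluded from mean OCDS_l but count as low
dynamics in the OCDS-LDV — a static voxel is precisely what the LDV is meant
to capture.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .doct_metrics import LIVMap, OCDSMap

__all__ = [
    "Cutoffs",
    "MetricsRecord",
    "spheroid_volume",
    "mean_in_mask",
    "low_dynamics_volume",
    "spheroid_centroid",
    "quantify_timepoint",
    "records_to_frame",
]


@dataclass(frozen=True)
class Cutoffs:
    """Low-dynamics cut-offs: LIV in dB², OCDS_l in ms⁻¹."""

    liv_db2: float = 3.0
    ocds_ms_inv: float = 2e-4

    def __post_init__(self) -> None:
        if not (self.liv_db2 > 0 and self.ocds_ms_inv > 0):
            raise ValueError("cutoffs must be > 0")


@dataclass
class MetricsRecord:
    """One row of the longitudinal metrics table."""

    sample_id: str
    condition: str
    concentration_um: float
    time_hr: float
    volume_um3: float
    mean_liv_db2: float
    liv_ldv_um3: float
    mean_ocds_ms_inv: float
    ocds_ldv_um3: float
    n_mask_voxels: int


def _voxel_volume_um3(voxel_size_um) -> float:
    vz, vy, vx = voxel_size_um
    return float(vz) * float(vy) * float(vx)


def spheroid_volume(mask: np.ndarray, voxel_size_um) -> float:
    """Foreground voxel count times voxel volume, in µm³."""
    return float(np.count_nonzero(mask)) * _voxel_volume_um3(voxel_size_um)


def mean_in_mask(
    values: np.ndarray, mask: np.ndarray, valid: np.ndarray | None = None
) -> float:
    """Arithmetic mean of ``values`` over valid foreground voxels."""
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError(f"shape mismatch: {values.shape} vs {mask.shape}")
    sel = mask if valid is None else (mask & np.asarray(valid, dtype=bool))
    if not sel.any():
        raise ValueError("mask is empty (no valid foreground voxels)")
    return float(values[sel].mean())


def low_dynamics_volume(
    values: np.ndarray,
    mask: np.ndarray,
    cutoff: float,
    voxel_size_um,
    valid: np.ndarray | None = None,
    invalid_counts_low: bool = False,
    inclusive: bool = False,
) -> float:
    """Volume of foreground voxels with metric value below the cut-off (µm³).

    ``invalid_counts_low`` treats invalid-flagged voxels (static, undefined
    OCDS_l) as low dynamics; otherwise they are ignored.  ``inclusive``
    switches the strict ``<`` to ``<=``.
    """
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError(f"shape mismatch: {values.shape} vs {mask.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    vox = _voxel_volume_um3(voxel_size_um)
    if valid is None:
        valid = np.isfinite(values)
    else:
        valid = np.asarray(valid, dtype=bool)
    low = values < cutoff if not inclusive else values <= cutoff
    low = low & valid & mask
    count = int(np.count_nonzero(low))
    if invalid_counts_low:
        count += int(np.count_nonzero(mask & ~valid))
    return count * vox


def spheroid_centroid(mask: np.ndarray) -> tuple[float, float, float]:
    """Foreground center of mass in voxel coordinates (z, y, x)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    idx = np.nonzero(mask)
    return tuple(float(np.mean(ax)) for ax in idx)


def quantify_timepoint(
    mask: np.ndarray,
    liv: LIVMap,
    ocds: OCDSMap,
    voxel_size_um,
    cutoffs: Cutoffs | None = None,
    sample_id: str = "sample",
    condition: str = "control",
    concentration_um: float = 0.0,
    time_hr: float = 0.0,
) -> MetricsRecord:
    """All scalar metrics of one sample at one timepoint."""
    c = cutoffs or Cutoffs()
    vol = spheroid_volume(mask, voxel_size_um)
    return MetricsRecord(
        sample_id=sample_id,
        condition=condition,
        concentration_um=concentration_um,
        time_hr=time_hr,
        volume_um3=vol,
        mean_liv_db2=mean_in_mask(liv.values, mask),
        liv_ldv_um3=low_dynamics_volume(liv.values, mask, c.liv_db2, voxel_size_um),
        mean_ocds_ms_inv=mean_in_mask(ocds.values, mask, valid=ocds.valid),
        ocds_ldv_um3=low_dynamics_volume(
            ocds.values, mask, c.ocds_ms_inv, voxel_size_um,
            valid=ocds.valid, invalid_counts_low=True,
        ),
        n_mask_voxels=int(np.count_nonzero(mask)),
    )


def records_to_frame(records) -> pd.DataFrame:
    """Long-format DataFrame, one row per sample x timepoint."""
    return pd.DataFrame([asdict(r) for r in records])
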
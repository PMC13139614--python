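"""Per-voxel dynamic-OCT metrics from repeated-frame intensity sequences.

Two fluctuation statistics are computed on the dB-scaled intensity time
series of each voxel:

* **LIV** (logarithmic intensity variance): the temporal variance of the
  dB-scaled intensity, in dB².  It contrasts the *amount* of signal
  fluctuation and is sensitive to the fraction of moving scatterers in the
  voxel.
* **OCDS_l** (late OCT correlation decay speed): minus the least-squares
  slope of the intensity autocorrelation over a late delay window
  (default 204.8–1228.8 ms), in ms⁻¹.  It contrasts *how fast* the signal
  decorrelates and is sensitive to scatterer speed within the window's band.

The autocorrelation estimator is the biased, common-mean form

    rho(k) = sum_{i=1..N-k} (I_i - Ibar)(I_{i+k} - Ibar) / sum_i (I_i - Ibar)^2

with ``Ibar`` the full-sequence mean.  For the short sequences used here
(N = 32) this estimator is preferred over per-lag-mean or unbiased variants
for its lower variance; it is tied down by brute-force oracle tests.

Voxels with zero temporal variance (perfectly static signal) have no defined
autocorrelation; they are flagged invalid and carry LIV = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scan_protocol import DelayGrid

__all__ = [
    "IntensitySequence",
    "LIVMap",
    "AutocorrSet",
    "OCDSMap",
    "to_db",
    "compute_liv",
    "compute_autocorr",
    "compute_ocds",
]


@dataclass
class IntensitySequence:
    """4-D dB-scaled intensity sequence: ``values[frame, z, y, x]``.

    ``timestamps_s`` are the revisit times of one B-scan location; they must
    be strictly increasing and equally spaced (within 1 ppm), as produced by
    the repeated-raster schedule.
    """

    values: np.ndarray
    timestamps_s: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(f"values must be 4-D (t, z, y, x), got shape {self.values.shape}")
        n = self.values.shape[0]
        if n < 2:
            raise ValueError("need at least 2 frames")
        if self.timestamps_s.shape != (n,):
            raise ValueError(
                f"timestamps length {self.timestamps_s.shape} does not match {n} frames"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")
        dt = np.diff(self.timestamps_s)
        if not np.all(dt > 0):
            raise ValueError("timestamps must be strictly increasing")
        if dt.size and (dt.max() - dt.min()) > 1e-6 * dt.mean():
            raise ValueError("timestamps must be equally spaced (within 1 ppm)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:]

    @property
    def frame_interval_ms(self) -> float:
        return float(np.diff(self.timestamps_s).mean() * 1000.0)

    def mean_db(self) -> np.ndarray:
        """Time-averaged dB intensity per voxel."""
        return self.values.mean(axis=0)


@dataclass
class LIVMap:
    """LIV volume (dB²) with provenance of the sequence it came from."""

    values: np.ndarray
    n_frames: int
    frame_interval_ms: float
    ddof: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("LIV values must be finite and >= 0")


@dataclass
class AutocorrSet:
    """Autocorrelation curves: ``curves[lag, z, y, x]`` at ``delays_ms``.

    ``valid`` is False where the voxel sequence had zero variance.
    """

    curves: np.ndarray
    delays_ms: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.curves.shape[0] != len(self.delays_ms):
            raise ValueError("curves first axis must match delay grid length")
        if self.valid.shape != self.curves.shape[1:]:
            raise ValueError("valid mask must match spatial shape")


@dataclass
class OCDSMap:
    """OCDS_l volume (ms⁻¹); NaN and ``valid=False`` where undefined."""

    values: np.ndarray
    valid: np.ndarray
    window_ms: tuple[float, float]


def to_db(intensity, floor: float) -> np.ndarray:
    """dB-scale a linear intensity: ``10 log10(max(I, floor))``.

    ``floor`` (> 0) clamps zero intensity so the log is defined; negative
    intensities are a contract violation of the noise model and raise.
    """
    if not floor > 0:
        raise ValueError("floor must be > 0")
    x = np.asarray(intensity, dtype=float)
    if np.any(x < 0):
        raise ValueError("linear intensity must be >= 0")
    return 10.0 * np.log10(np.maximum(x, floor))


def compute_liv(seq: IntensitySequence, ddof: int = 0) -> LIVMap:
    """Temporal variance of the dB intensity per voxel.

    ``ddof=0`` (population variance, divisor N) is the default convention;
    ``ddof=1`` switches to the sample variance.
    """
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")
    liv = seq.values.var(axis=0, ddof=ddof)
    # guard tiny negative round-off
    np.maximum(liv, 0.0, out=liv)
    return LIVMap(
        values=liv, n_frames=seq.n_frames, frame_interval_ms=seq.frame_interval_ms, ddof=ddof
    )


def compute_autocorr(seq: IntensitySequence, grid: DelayGrid) -> AutocorrSet:
    """Biased common-mean autocorrelation at each grid delay, per voxel.

    The grid delays must be the first ``L`` multiples of the sequence's frame
    interval with ``L < n_frames``.  Zero-variance voxels are flagged invalid
    and their curves set to NaN.
    """
    delays = np.asarray(grid.delays_ms, dtype=float)
    n = seq.n_frames
    dt_ms = seq.frame_interval_ms
    lags = delays / dt_ms
    lag_ints = np.rint(lags).astype(int)
    if not np.allclose(lags, lag_ints, atol=1e-6):
        raise ValueError("delay grid is not an integer multiple of the frame interval")
    if lag_ints.max() >= n:
        raise ValueError(f"max lag {lag_ints.max()} must be < n_frames = {n}")
    x = seq.values - seq.values.mean(axis=0, keepdims=True)
    denom = (x * x).sum(axis=0)
    valid = denom > 0
    safe = np.where(valid, denom, 1.0)
    curves = np.empty((len(lag_ints),) + seq.grid_shape, dtype=float)
    for i, k in enumerate(lag_ints):
        num = (x[: n - k] * x[k:]).sum(axis=0)
        curves[i] = np.where(valid, num / safe, np.nan)
    return AutocorrSet(curves=curves, delays_ms=delays, valid=valid)


def compute_ocds(
    ac: AutocorrSet, window_ms: tuple[float, float] | None = None
) -> OCDSMap:
    """OCDS_l: minus the OLS slope of rho(tau) over the late delay window.

    A decaying correlation has a negative slope, so OCDS_l is positive for
    dynamic voxels — faster decay within the window gives a larger value.
    Invalid (zero-variance) voxels propagate as NaN/invalid.
    """
    if window_ms is None:
        raise ValueError("an OCDS window must be supplied (e.g. (204.8, 1228.8) ms)")
    lo, hi = window_ms
    d = ac.delays_ms
    eps = 1e-9 * max(abs(hi), 1.0)
    sel = (d >= lo - eps) & (d <= hi + eps)
    if sel.sum() < 2:
        raise ValueError(f"OCDS window [{lo}, {hi}] ms contains fewer than 2 grid delays")
    tau = d[sel]
    rho = ac.curves[sel]
    tau_c = tau - tau.mean()
    sxx = float((tau_c**2).sum())
    slope = np.tensordot(tau_c, rho, axes=(0, 0)) / sxx
    values = np.where(ac.valid, -slope, np.nan)
    return OCDSMap(values=values, valid=ac.valid.copy(), window_ms=(float(lo), float(hi)))
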
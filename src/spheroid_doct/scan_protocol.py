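"""Interleaved block-raster acquisition timing and longitudinal study schedules.

A dynamic-OCT volume is acquired as a set of *blocks* (lateral sub-fields).
Each block holds a fixed number of B-scan locations that are visited in an
interleaved repeated raster: one raster pass images every location in the
block once, and the pass is repeated ``n_repeats`` times, so each location is
revisited with a fixed period (the inter-frame interval).  The per-voxel
fluctuation statistics (LIV, OCDS_l) are computed from the resulting
equally-spaced intensity time series at each location.

Timestamps are represented internally as exact rational multiples of the
per-frame slot (:class:`fractions.Fraction`) so that schedule invariants —
for example, that consecutive revisits of one location differ by exactly the
inter-frame interval — hold without floating-point drift.  Conversion to
float seconds happens only at the array/export boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "ScanProtocol",
    "FrameSchedule",
    "DelayGrid",
    "StudySchedule",
    "InvalidProtocolError",
    "build_schedule",
    "block_duration",
    "volume_duration",
    "delay_grid",
    "study_timepoints",
]


class InvalidProtocolError(ValueError):
    """Raised when scan-protocol parameters are inconsistent."""


def _as_fraction(x) -> Fraction:
    """Exact Fraction from an int/float/str given with decimal intent."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


@dataclass(frozen=True)
class ScanProtocol:
    """Repeated-raster acquisition parameters.

    Defaults describe the reference protocol: a 1 x 1 mm field split into
    8 blocks of 16 B-scan locations, 32 repeats per location at a 204.8 ms
    revisit period (4096 frames per volume, 52.4 s).

    Parameters
    ----------
    n_blocks : int
        Number of lateral sub-fields scanned sequentially.
    locations_per_block : int
        B-scan locations interleaved within one block.
    n_repeats : int
        Frames captured at each location.
    inter_frame_interval_ms : float
        Revisit period of a single location, in milliseconds.
    field_size_mm : tuple of float
        Lateral field extent (metadata only).
    aline_rate_hz : float
        A-line rate of the source (metadata only; A-lines per frame are not
        modeled).
    """

    n_blocks: int = 8
    locations_per_block: int = 16
    n_repeats: int = 32
    inter_frame_interval_ms: float = 204.8
    field_size_mm: tuple[float, float] = (1.0, 1.0)
    aline_rate_hz: float = 50_000.0

    def __post_init__(self) -> None:
        for name in ("n_blocks", "locations_per_block", "n_repeats"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise InvalidProtocolError(f"{name} must be a positive integer, got {v!r}")
        if not float(self.inter_frame_interval_ms) > 0:
            raise InvalidProtocolError(
                f"inter_frame_interval_ms must be > 0, got {self.inter_frame_interval_ms!r}"
            )

    @property
    def interval_ms(self) -> Fraction:
        """Inter-frame interval as an exact Fraction of ms."""
        return _as_fraction(self.inter_frame_interval_ms)

    @property
    def per_frame_slot_ms(self) -> Fraction:
        """Time slot of one frame: interval / locations_per_block (ms)."""
        return self.interval_ms / self.locations_per_block

    @property
    def total_locations(self) -> int:
        return self.n_blocks * self.locations_per_block

    @property
    def frames_per_volume(self) -> int:
        return self.total_locations * self.n_repeats


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition-ordered frame timing for one volume.

    ``entries`` holds ``(block, location, repeat, t_s)`` with ``t_s`` an exact
    :class:`~fractions.Fraction` in seconds.
    """

    protocol: ScanProtocol
    entries: tuple[tuple[int, int, int, Fraction], ...]

    @property
    def per_frame_slot_ms(self) -> Fraction:
        return self.protocol.per_frame_slot_ms

    def timestamps_s(self) -> np.ndarray:
        """All frame timestamps in acquisition order, float seconds."""
        return np.array([float(e[3]) for e in self.entries])

    def location_timestamps_s(self, block: int, location: int) -> np.ndarray:
        """The ``n_repeats`` revisit timestamps of one B-scan location (s)."""
        ts = [float(e[3]) for e in self.entries if e[0] == block and e[1] == location]
        if not ts:
            raise KeyError(f"no such location: block={block}, location={location}")
        return np.array(ts)

    def relative_location_timestamps_s(self) -> np.ndarray:
        """Revisit timestamps of a location relative to its first frame (s).

        Identical for every location: ``k * inter_frame_interval``,
        k = 0..n_repeats-1.
        """
        p = self.protocol
        slot_s = p.interval_ms / 1000
        return np.array([float(k * slot_s) for k in range(p.n_repeats)])

    def to_records(self) -> list[dict]:
        return [
            {"block": b, "location": loc, "repeat": r, "t_s": float(t)}
            for b, loc, r, t in self.entries
        ]


def build_schedule(protocol: ScanProtocol) -> FrameSchedule:
    """Enumerate the interleaved repeated-raster schedule.

    Blocks are acquired sequentially.  Within a block, each raster pass visits
    every location once; the pass is repeated ``n_repeats`` times, so one
    location's revisit period is exactly the inter-frame interval.  Frame *k*
    (acquisition order) starts at ``k * per_frame_slot``.
    """
    slot_s = protocol.per_frame_slot_ms / 1000
    entries = []
    k = 0
    for b in range(protocol.n_blocks):
        for r in range(protocol.n_repeats):
            for loc in range(protocol.locations_per_block):
                entries.append((b, loc, r, k * slot_s))
                k += 1
    return FrameSchedule(protocol=protocol, entries=tuple(entries))


def block_duration(protocol: ScanProtocol) -> float:
    """Duration of one block's repeated raster, in seconds."""
    return float(protocol.n_repeats * protocol.interval_ms / 1000)


def volume_duration(protocol: ScanProtocol) -> float:
    """Acquisition span of one full volume, in seconds."""
    return protocol.n_blocks * block_duration(protocol)


@dataclass(frozen=True)
class DelayGrid:
    """Lag-time grid for the intensity autocorrelation.

    ``delays_ms`` are the positive multiples of the inter-frame interval at
    which the autocorrelation is evaluated; ``ocds_window_ms`` is the late
    delay range over which the decay slope (OCDS_l) is fitted.
    """

    delays_ms: tuple[float, ...]
    ocds_window_ms: tuple[float, float] | None

    def __post_init__(self) -> None:
        d = np.asarray(self.delays_ms)
        if d.ndim != 1 or len(d) < 1 or not np.all(np.diff(d) > 0):
            raise ValueError("delays must be a strictly increasing 1-D sequence")
        if self.ocds_window_ms is None:
            return
        lo, hi = self.ocds_window_ms
        if not lo < hi:
            raise ValueError("ocds window lower bound must be below upper bound")
        for bound in (lo, hi):
            if not np.any(np.isclose(d, bound, rtol=1e-9)):
                raise ValueError(f"ocds window bound {bound} ms is not on the delay grid")

    def window_delays_ms(self) -> np.ndarray:
        if self.ocds_window_ms is None:
            raise ValueError("delay grid has no OCDS window (fewer than 2 lags)")
        d = np.asarray(self.delays_ms)
        lo, hi = self.ocds_window_ms
        eps = 1e-9 * max(abs(hi), 1.0)
        return d[(d >= lo - eps) & (d <= hi + eps)]


def delay_grid(
    protocol: ScanProtocol,
    max_lag: int,
    ocds_window_ms: tuple[float, float] | None = None,
) -> DelayGrid:
    """Delay grid ``{k * interval : k = 1..max_lag}`` for a protocol.

    The default OCDS window spans lags 1..6 (204.8–1228.8 ms at the reference
    interval), clipped to ``max_lag`` if fewer lags are available.
    """
    if not 1 <= max_lag <= protocol.n_repeats - 1:
        raise ValueError(
            f"max_lag must be in [1, n_repeats-1] = [1, {protocol.n_repeats - 1}], got {max_lag}"
        )
    iv = protocol.interval_ms
    delays = tuple(float(k * iv) for k in range(1, max_lag + 1))
    if ocds_window_ms is None:
        if max_lag >= 2:
            ocds_window_ms = (float(iv), float(min(6, max_lag) * iv))
        # max_lag == 1: no window — OCDS fit needs >= 2 delays
    return DelayGrid(delays_ms=delays, ocds_window_ms=ocds_window_ms)


@dataclass(frozen=True)
class StudySchedule:
    """Longitudinal imaging grid: inclusive timepoints 0..duration (hours)."""

    duration_hr: float
    interval_hr: float
    timepoints_hr: tuple[float, ...]

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints_hr)


def study_timepoints(duration_hr: float, interval_hr: float) -> StudySchedule:
    """Inclusive timepoint grid ``{0, dt, 2 dt, ..., duration}``.

    The reference studies image over 100 h at 4 h (26 timepoints) or 30 min
    (201 timepoints) intervals.
    """
    if duration_hr < 0 or interval_hr <= 0:
        raise ValueError("duration must be >= 0 and interval > 0")
    if duration_hr == 0:
        return StudySchedule(duration_hr=0.0, interval_hr=float(interval_hr), timepoints_hr=(0.0,))
    dur = _as_fraction(duration_hr)
    iv = _as_fraction(interval_hr)
    n = dur / iv
    if n.denominator != 1:
        raise ValueError(
            f"duration ({duration_hr} hr) is not divisible by interval ({interval_hr} hr)"
        )
    pts = tuple(float(k * iv) for k in range(int(n) + 1))
    return StudySchedule(
        duration_hr=float(duration_hr), interval_hr=float(interval_hr), timepoints_hr=pts
    )
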
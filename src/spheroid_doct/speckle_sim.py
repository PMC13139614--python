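"""Dynamic-speckle synthetic data: voxel time series, spheroid phantoms,
longitudinal drug-response scenarios.

Generator model
---------------
Each voxel's complex OCT field is a random-phasor sum with a static and a
dynamic part,

    E(t) = sqrt(B) * [ sqrt(1-f) * E_static + sqrt(f) * E_dyn(t) ],

where ``f`` is the *dynamic fraction* (share of backscattered power from
moving scatterers), ``B`` the mean backscatter intensity, ``E_static`` a
fixed unit-power phasor with a random phase, and ``E_dyn`` a sum of
``n_phasors`` unit-power phasors whose phases perform independent Gaussian
random walks.  The walk step variance is calibrated so that the ensemble
field autocorrelation is

    g1(tau) = (1 - f) + f * exp(-tau / tau_c),

with ``tau_c`` the 1/e decorrelation time of the dynamic field.  Measured
intensity is ``|E|^2`` plus an exponentially distributed noise term (mean
``noise_floor``), which preserves speckle-like statistics in the background.
Voxels are statistically independent; LIV and OCDS_l are per-voxel
statistics, so lateral speckle correlation is irrelevant to their contracts.

The dynamic fraction drives the dB-intensity variance (LIV) and the
decorrelation time drives the correlation decay (OCDS_l), which are the two
sensitivities the pipeline's metrics are designed to read out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .doct_metrics import IntensitySequence, to_db

__all__ = [
    "VoxelDynamics",
    "Phantom",
    "TimeLapseScenario",
    "ScenarioParams",
    "CONDITIONS",
    "simulate_field_sequence",
    "render_intensity",
    "render_location_sequence",
    "render_phantom_sequence",
    "make_spheroid_phantom",
    "make_timelapse",
]

#: recognised longitudinal scenario labels
CONDITIONS = ("control", "dox_like", "tam_like", "ptx_like")

#: linear-intensity floor used when dB-scaling rendered sequences
DB_FLOOR = 1e-3


@dataclass(frozen=True)
class VoxelDynamics:
    """Dynamics of one voxel (or a tissue class).

    dynamic_fraction
        Share of backscattered power from moving scatterers, in [0, 1].
    decorrelation_time_ms
        1/e time of the dynamic field autocorrelation (> 0).
    backscatter
        Mean linear intensity (>= 0), arbitrary linear units.
    """

    dynamic_fraction: float
    decorrelation_time_ms: float
    backscatter: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dynamic_fraction <= 1.0:
            raise ValueError(f"dynamic_fraction must be in [0, 1], got {self.dynamic_fraction}")
        if not self.decorrelation_time_ms > 0:
            raise ValueError("decorrelation_time_ms must be > 0")
        if self.backscatter < 0:
            raise ValueError("backscatter must be >= 0")


@dataclass
class Phantom:
    """3-D grid of per-voxel dynamics plus geometry ground truth.

    Arrays are indexed ``[z, y, x]``.  ``sphere_mask``/``core_mask``/
    ``plate_mask`` record the generative geometry for validation against the
    segmentation and quantification stages.
    """

    dynamic_fraction: np.ndarray
    decorrelation_time_ms: np.ndarray
    backscatter: np.ndarray
    voxel_size_um: tuple[float, float, float]
    noise_floor: float
    sphere_center_um: tuple[float, float, float]
    sphere_radius_um: float
    core_radius_um: float
    plate_z_index: int | None
    sphere_mask: np.ndarray = field(repr=False, default=None)
    core_mask: np.ndarray = field(repr=False, default=None)
    plate_mask: np.ndarray = field(repr=False, default=None)
    low_dynamics_mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        shp = self.dynamic_fraction.shape
        for name in ("decorrelation_time_ms", "backscatter"):
            if getattr(self, name).shape != shp:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shp}")
        f = self.dynamic_fraction
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("dynamic_fraction must lie in [0, 1]")
        if np.any(self.decorrelation_time_ms <= 0):
            raise ValueError("decorrelation_time_ms must be > 0 everywhere")
        if np.any(self.backscatter < 0):
            raise ValueError("backscatter must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.dynamic_fraction.shape


def _phase_step_sigma(dt_ms: np.ndarray | float, tau_ms: np.ndarray) -> np.ndarray:
    """Std of the phase random-walk increment for a step of ``dt_ms``.

    A Gaussian phase increment with variance ``2 dt / tau_c`` gives
    ``E[exp(i dphi)] = exp(-dt / tau_c)``, hence an exponential field
    autocorrelation with 1/e time ``tau_c``.
    """
    return np.sqrt(2.0 * np.asarray(dt_ms, dtype=float) / tau_ms)


def simulate_field_sequence(
    dynamic_fraction: np.ndarray | float,
    decorrelation_time_ms: np.ndarray | float,
    backscatter: np.ndarray | float,
    timestamps_s: Sequence[float],
    n_phasors: int = 16,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Complex field time series for an array of independent voxels.

    Parameters may be scalars or broadcastable arrays; the result has shape
    ``(n_frames,) + voxel_shape``.  The ensemble field autocorrelation is
    ``B * [(1-f) + f exp(-tau/tau_c)]`` and the mean intensity is ``B``.
    """
    ts = np.asarray(timestamps_s, dtype=float)
    if ts.size == 0:
        raise ValueError("timestamps must be non-empty")
    if ts.ndim != 1 or (ts.size > 1 and not np.all(np.diff(ts) > 0)):
        raise ValueError("timestamps must be a strictly increasing 1-D sequence")
    if n_phasors < 8:
        raise ValueError("n_phasors must be >= 8 for acceptable phasor-sum statistics")
    f, tau, B = np.broadcast_arrays(
        np.asarray(dynamic_fraction, dtype=float),
        np.asarray(decorrelation_time_ms, dtype=float),
        np.asarray(backscatter, dtype=float),
    )
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("dynamic_fraction must lie in [0, 1]")
    if np.any(tau <= 0):
        raise ValueError("decorrelation_time_ms must be > 0")
    rng = np.random.default_rng(rng)
    shape = f.shape
    n_vox = int(np.prod(shape)) if shape else 1
    f_flat = f.reshape(n_vox)
    tau_flat = tau.reshape(n_vox)
    B_flat = B.reshape(n_vox)

    # static part: one fixed random phasor per voxel, unit power
    e_static = np.exp(1j * rng.uniform(0.0, 2.0 * np.pi, size=n_vox)).astype(np.complex64)

    # dynamic phasor walks are only needed where f > 0; purely static voxels
    # keep their fixed phasor.  float32 phases keep the walk cheap; the
    # statistics of interest are ensemble moments, far above float32 noise.
    active = f_flat > 0
    n_act = int(active.sum())
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_phasors, n_act)).astype(np.float32)
    tau_act = tau_flat[active].astype(np.float32)

    amp = np.sqrt(B_flat).astype(np.float32)
    w_static = np.sqrt(1.0 - f_flat).astype(np.float32)
    w_dyn_act = np.sqrt(f_flat[active]).astype(np.float32)
    norm = np.float32(1.0 / np.sqrt(n_phasors))
    static_term = (amp * w_static) * e_static

    out = np.empty((ts.size, n_vox), dtype=np.complex64)
    prev_t = ts[0]
    for i, t in enumerate(ts):
        if i > 0:
            dt_ms = np.float32((t - prev_t) * 1000.0)
            sigma = _phase_step_sigma(dt_ms, tau_act).astype(np.float32)
            phases += rng.standard_normal(size=phases.shape, dtype=np.float32) * sigma
            prev_t = t
        e_dyn = (np.cos(phases).sum(axis=0) + 1j * np.sin(phases).sum(axis=0)) * norm
        frame = static_term.copy()
        frame[active] += (amp[active] * w_dyn_act) * e_dyn.astype(np.complex64)
        out[i] = frame
    return out.reshape((ts.size,) + shape)


def render_intensity(
    field: np.ndarray,
    noise_floor: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Detected linear intensity: ``|E|^2`` plus exponential noise."""
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")
    intensity = np.abs(field) ** 2
    if noise_floor > 0:
        intensity = intensity + rng.exponential(noise_floor, size=field.shape)
    return intensity


def render_location_sequence(
    phantom: Phantom,
    y_index: int,
    timestamps_s: Sequence[float],
    n_phasors: int = 16,
    rng: np.random.Generator | int | None = None,
    db_floor: float = DB_FLOOR,
) -> IntensitySequence:
    """Render the repeated-frame dB sequence of one B-scan location (fixed y).

    Returns an :class:`IntensitySequence` of shape ``(T, z, 1, x)``.
    """
    ts = np.asarray(timestamps_s, dtype=float)
    if ts.size < 2:
        raise ValueError("need at least 2 timestamps")
    rng = np.random.default_rng(rng)
    sl = (slice(None), slice(y_index, y_index + 1), slice(None))
    fld = simulate_field_sequence(
        phantom.dynamic_fraction[sl],
        phantom.decorrelation_time_ms[sl],
        phantom.backscatter[sl],
        ts,
        n_phasors=n_phasors,
        rng=rng,
    )
    intensity = render_intensity(fld, phantom.noise_floor, rng)
    return IntensitySequence(
        values=to_db(intensity, db_floor), timestamps_s=ts, voxel_size_um=phantom.voxel_size_um
    )


def render_phantom_sequence(
    phantom: Phantom,
    timestamps_s: Sequence[float],
    n_phasors: int = 16,
    rng: np.random.Generator | int | None = None,
    db_floor: float = DB_FLOOR,
) -> IntensitySequence:
    """Render the full-volume repeated-frame dB sequence.

    Every B-scan location shares the same revisit timestamps relative to its
    first frame (the repeated-raster schedule guarantees this), and the
    per-voxel statistics depend only on those relative lags, so the whole
    volume is rendered against one timestamp vector.
    """
    ts = np.asarray(timestamps_s, dtype=float)
    if ts.size < 2:
        raise ValueError("need at least 2 timestamps")
    rng = np.random.default_rng(rng)
    fld = simulate_field_sequence(
        phantom.dynamic_fraction,
        phantom.decorrelation_time_ms,
        phantom.backscatter,
        ts,
        n_phasors=n_phasors,
        rng=rng,
    )
    intensity = render_intensity(fld, phantom.noise_floor, rng)
    return IntensitySequence(
        values=to_db(intensity, db_floor), timestamps_s=ts, voxel_size_um=phantom.voxel_size_um
    )


# ---------------------------------------------------------------------------
# phantom construction

# Default tissue classes.  Viable tissue: most backscatter from moving
# scatterers, decorrelating within the late OCDS window (high LIV, high
# OCDS_l).  Low-dynamics (dead) tissue: a small residual fraction of fast,
# weak jitter (debris), giving both low LIV and a near-flat late-window
# correlation (low OCDS_l).  Culture medium: static, dim.  Well-plate
# surface: static, bright.
VIABLE = VoxelDynamics(dynamic_fraction=0.8, decorrelation_time_ms=1200.0, backscatter=100.0)
LOW_DYNAMICS = VoxelDynamics(dynamic_fraction=0.02, decorrelation_time_ms=100.0, backscatter=100.0)
MEDIUM = VoxelDynamics(dynamic_fraction=0.0, decorrelation_time_ms=1000.0, backscatter=0.02)
PLATE = VoxelDynamics(dynamic_fraction=0.0, decorrelation_time_ms=1000.0, backscatter=1000.0)

DEFAULT_NOISE_FLOOR = 0.01


def make_spheroid_phantom(
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size_um: tuple[float, float, float] = (5.0, 5.0, 5.0),
    sphere_radius_um: float = 90.0,
    core_radius_um: float = 0.0,
    center_um: tuple[float, float, float] | None = None,
    shell: VoxelDynamics = VIABLE,
    core: VoxelDynamics = LOW_DYNAMICS,
    medium: VoxelDynamics = MEDIUM,
    plate: VoxelDynamics = PLATE,
    plate_z_index: int | None = None,
    n_spots: int = 0,
    spot_radius_um: float = 15.0,
    spot_centers_um: np.ndarray | None = None,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    rng: np.random.Generator | int | None = None,
) -> Phantom:
    """Spherical spheroid phantom with viable shell, optional low-dynamics
    core and spots, culture-medium background and a static bright plate plane.

    The sphere must fit inside the grid; the core must fit inside the sphere.
    Spot centers may be supplied explicitly (for persistent spots across a
    time-lapse) or drawn uniformly inside the sphere.
    """
    nz, ny, nx = grid_shape
    vz, vy, vx = voxel_size_um
    if core_radius_um > sphere_radius_um:
        raise ValueError("core radius must not exceed sphere radius")
    if center_um is None:
        center_um = ((nz - 1) * vz / 2.0, (ny - 1) * vy / 2.0, (nx - 1) * vx / 2.0)
    cz, cy, cx = center_um
    for c, n, v, r in ((cz, nz, vz, sphere_radius_um), (cy, ny, vy, sphere_radius_um),
                       (cx, nx, vx, sphere_radius_um)):
        if c - r < -v / 2 or c + r > (n - 0.5) * v:
            raise ValueError("sphere does not fit inside the grid")
    z = np.arange(nz)[:, None, None] * vz
    y = np.arange(ny)[None, :, None] * vy
    x = np.arange(nx)[None, None, :] * vx
    r2 = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2
    sphere = r2 <= sphere_radius_um**2
    core_mask = r2 <= core_radius_um**2 if core_radius_um > 0 else np.zeros_like(sphere)

    rng = np.random.default_rng(rng)
    spots = np.zeros_like(sphere)
    if n_spots > 0:
        if spot_centers_um is None:
            spot_centers_um = _draw_spot_centers(
                rng, n_spots, center_um, sphere_radius_um, spot_radius_um
            )
        for sc in np.asarray(spot_centers_um)[:n_spots]:
            d2 = (z - sc[0]) ** 2 + (y - sc[1]) ** 2 + (x - sc[2]) ** 2
            spots |= d2 <= spot_radius_um**2
        spots &= sphere

    f = np.full(grid_shape, medium.dynamic_fraction)
    tau = np.full(grid_shape, medium.decorrelation_time_ms)
    back = np.full(grid_shape, medium.backscatter)
    low = (core_mask | spots) & sphere
    shell_mask = sphere & ~low
    for mask, cls in ((shell_mask, shell), (low, core)):
        f[mask] = cls.dynamic_fraction
        tau[mask] = cls.decorrelation_time_ms
        back[mask] = cls.backscatter

    plate_mask = np.zeros_like(sphere)
    if plate_z_index is not None:
        plate_mask[plate_z_index, :, :] = True
        plate_mask &= ~sphere  # spheroid rests on the plate; tissue wins
        f[plate_mask] = plate.dynamic_fraction
        tau[plate_mask] = plate.decorrelation_time_ms
        back[plate_mask] = plate.backscatter

    return Phantom(
        dynamic_fraction=f,
        decorrelation_time_ms=tau,
        backscatter=back,
        voxel_size_um=voxel_size_um,
        noise_floor=noise_floor,
        sphere_center_um=tuple(float(c) for c in center_um),
        sphere_radius_um=float(sphere_radius_um),
        core_radius_um=float(core_radius_um),
        plate_z_index=plate_z_index,
        sphere_mask=sphere,
        core_mask=core_mask,
        plate_mask=plate_mask,
        low_dynamics_mask=low,
    )


def _draw_spot_centers(rng, n_spots, center_um, sphere_radius_um, spot_radius_um):
    """Uniform spot centers inside the sphere (kept off the rim)."""
    max_r = max(sphere_radius_um - spot_radius_um, 0.3 * sphere_radius_um)
    u = rng.uniform(0.0, 1.0, size=n_spots)
    radii = max_r * u ** (1.0 / 3.0)
    vec = rng.standard_normal((n_spots, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return np.asarray(center_um)[None, :] + radii[:, None] * vec


# ---------------------------------------------------------------------------
# longitudinal scenarios


@dataclass(frozen=True)
class ScenarioParams:
    """Generative parameters of a longitudinal drug-response scenario.

    Growth is volumetric and linear in time (radius ~ cube root); treated
    conditions modify growth and/or dynamics from ``onset_hr`` on:

    control   — steady growth, uniform viable dynamics.
    dox_like  — growth suppressed after onset; a central low-dynamics core
                appears at onset and expands.
    tam_like  — growth rate reduced after onset; dynamics unchanged.
    ptx_like  — growth arrest after onset; scattered low-dynamics spots
                accumulate over time.
    """

    initial_radius_um: float = 80.0
    growth_rate_per_hr: float = 0.02  # fractional volume increase per hour
    onset_hr: float = 32.0
    suppressed_growth_factor: float = 0.25  # tam_like growth multiplier
    core_expansion_um_per_hr: float = 1.0  # dox_like core radius growth
    spot_rate_per_hr: float = 0.25  # ptx_like new spots per hour
    spot_radius_um: float = 15.0
    shell: VoxelDynamics = VIABLE
    core: VoxelDynamics = LOW_DYNAMICS
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_um: tuple[float, float, float] = (5.0, 5.0, 5.0)
    plate_z_index: int | None = 2
    noise_floor: float = DEFAULT_NOISE_FLOOR


@dataclass
class TimeLapseScenario:
    """A labelled longitudinal sequence of phantoms."""

    condition: str
    params: ScenarioParams
    frames: list[tuple[float, Phantom]]

    @property
    def times_hr(self) -> list[float]:
        return [t for t, _ in self.frames]


def _radius_at(p: ScenarioParams, condition: str, t_hr: float) -> float:
    """Radius trajectory: linear volumetric growth, condition-modified."""
    g = p.growth_rate_per_hr

    def vol_factor(t_effective: float) -> float:
        return 1.0 + g * t_effective

    if condition == "control" or t_hr <= p.onset_hr:
        vf = vol_factor(t_hr)
    elif condition == "tam_like":
        vf = vol_factor(p.onset_hr + p.suppressed_growth_factor * (t_hr - p.onset_hr))
    else:  # dox_like, ptx_like: growth arrest after onset
        vf = vol_factor(p.onset_hr)
    return p.initial_radius_um * vf ** (1.0 / 3.0)


def make_timelapse(
    condition: str,
    times_hr: Iterable[float],
    params: ScenarioParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> TimeLapseScenario:
    """Generate the phantom sequence of one longitudinal scenario.

    Spot centers are drawn once and accumulate, so low-dynamics spots persist
    between timepoints.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    p = params or ScenarioParams()
    times = [float(t) for t in times_hr]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)

    max_spots = 0
    if condition == "ptx_like" and times:
        max_spots = int(np.ceil(p.spot_rate_per_hr * max(max(times) - p.onset_hr, 0.0)))
    # persistent spot centers, drawn inside the *initial* sphere so they stay
    # inside as the sphere can only stay or grow before arrest
    spot_centers = (
        _draw_spot_centers(
            rng, max_spots,
            _grid_center_um(p), p.initial_radius_um, p.spot_radius_um,
        )
        if max_spots > 0
        else None
    )

    frames = []
    for t in times:
        radius = _radius_at(p, condition, t)
        core_r = 0.0
        n_spots = 0
        if condition == "dox_like" and t > p.onset_hr:
            core_r = min(p.core_expansion_um_per_hr * (t - p.onset_hr), 0.9 * radius)
        if condition == "ptx_like" and t > p.onset_hr:
            n_spots = int(np.floor(p.spot_rate_per_hr * (t - p.onset_hr)))
        phantom = make_spheroid_phantom(
            grid_shape=p.grid_shape,
            voxel_size_um=p.voxel_size_um,
            sphere_radius_um=radius,
            core_radius_um=core_r,
            shell=p.shell,
            core=p.core,
            plate_z_index=p.plate_z_index,
            n_spots=n_spots,
            spot_radius_um=p.spot_radius_um,
            spot_centers_um=spot_centers,
            noise_floor=p.noise_floor,
            rng=rng,
        )
        frames.append((t, phantom))
    return TimeLapseScenario(condition=condition, params=p, frames=frames)


def _grid_center_um(p: ScenarioParams) -> tuple[float, float, float]:
    nz, ny, nx = p.grid_shape
    vz, vy, vx = p.voxel_size_um
    return ((nz - 1) * vz / 2.0, (ny - 1) * vy / 2.0, (nx - 1) * vx / 2.0)
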
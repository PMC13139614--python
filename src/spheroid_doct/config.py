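"""Pipeline configuration: YAML/JSON block -> validated dataclasses.

Unknown keys are rejected so that typos fail loudly instead of silently
falling back to defaults.  The seed recorded here is propagated into every
artifact sidecar.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .quantify import Cutoffs
from .scan_protocol import ScanProtocol
from .segmentation import SegmentationParams
from .speckle_sim import ScenarioParams

__all__ = ["ConfigError", "MetricSettings", "StatsSettings", "PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class MetricSettings:
    """LIV/OCDS computation settings."""

    liv_ddof: int = 0  # 0 = population variance, 1 = sample variance
    max_lag: int = 6
    ocds_window_ms: tuple[float, float] = (204.8, 1228.8)

    def __post_init__(self) -> None:
        if self.liv_ddof not in (0, 1):
            raise ConfigError("liv_ddof must be 0 or 1")
        if self.max_lag < 2:
            raise ConfigError("max_lag must be >= 2 for an OCDS fit")


@dataclass(frozen=True)
class StatsSettings:
    """Which metrics/timepoints the report stage tests."""

    metrics: tuple[str, ...] = (
        "volume_um3",
        "mean_liv_db2",
        "liv_ldv_um3",
        "mean_ocds_ms_inv",
        "ocds_ldv_um3",
    )
    times_hr: tuple[float, ...] = (0.0, 12.0, 100.0)
    alpha: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level pipeline configuration."""

    protocol: ScanProtocol = field(default_factory=ScanProtocol)
    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    metrics: MetricSettings = field(default_factory=MetricSettings)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    stats: StatsSettings = field(default_factory=StatsSettings)
    seed: int = 0
    n_phasors: int = 16
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "protocol": ScanProtocol,
    "scenario": ScenarioParams,
    "metrics": MetricSettings,
    "segmentation": SegmentationParams,
    "cutoffs": Cutoffs,
    "stats": StatsSettings,
}
_SCALARS = {"seed": int, "n_phasors": int, "output_dir": str}

# keys whose YAML lists must become tuples to match dataclass field types
_TUPLE_KEYS = {
    "field_size_mm", "ocds_window_ms", "grid_shape", "voxel_size_um",
    "metrics", "times_hr",
}


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in '{section}': {sorted(unknown)} (allowed: {sorted(names)})")
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_KEYS and isinstance(v, (list, tuple)):
            v = tuple(v)
        elif k in ("shell", "core") and isinstance(v, dict):
            from .speckle_sim import VoxelDynamics

            v = _build_section(VoxelDynamics, v, f"{section}.{k}")
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' section: {exc}") from exc


def load_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML path, text, or dict."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, dict):
        data = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data[name]
            if not isinstance(section, dict):
                raise ConfigError(f"'{name}' must be a mapping")
            kwargs[name] = _build_section(cls, section, name)
    for name, typ in _SCALARS.items():
        if name in data:
            kwargs[name] = typ(data[name])
    return PipelineConfig(**kwargs)
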
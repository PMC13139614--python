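"""Volume/map interchange: multi-page TIFF stacks with JSON sidecars.

A 4-D intensity sequence is written frame-major (axes ``TZYX``) as a
multi-page TIFF; the sidecar JSON next to it records the acquisition
timestamps, voxel size, axes and provenance (seed, config hash, software
version).  3-D maps and 8-bit masks use the same pattern with axes ``ZYX``.
Round-trips are bit-exact.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .doct_metrics import IntensitySequence

__all__ = [
    "MissingSidecarError",
    "ShapeMismatchError",
    "TimestampError",
    "sidecar_path",
    "write_volume_sequence",
    "read_volume_sequence",
    "write_map",
    "read_map",
    "write_mask",
    "config_hash",
]


class MissingSidecarError(FileNotFoundError):
    """The JSON sidecar next to a TIFF stack is absent."""


class ShapeMismatchError(ValueError):
    """TIFF data shape disagrees with its sidecar metadata."""


class TimestampError(ValueError):
    """Sidecar timestamps are not strictly increasing."""


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(seed=None, extra=None) -> dict:
    meta = {"software": "spheroid-doct", "version": __version__}
    if seed is not None:
        meta["seed"] = int(seed)
    if extra:
        meta.update(extra)
    return meta


def write_volume_sequence(path, seq: IntensitySequence, seed=None, extra_meta=None) -> Path:
    """Write a 4-D dB sequence as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(seq.values, dtype=np.float32)
    tifffile.imwrite(path, data, metadata={"axes": "TZYX"})
    meta = {
        "axes": "TZYX",
        "shape": list(data.shape),
        "dtype": "float32",
        "units": "dB",
        "timestamps_s": [float(t) for t in seq.timestamps_s],
        "voxel_size_um": list(seq.voxel_size_um),
        "provenance": _provenance(seed, extra_meta),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_volume_sequence(path) -> IntensitySequence:
    """Read and validate a sequence written by :func:`write_volume_sequence`."""
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise MissingSidecarError(f"no sidecar {sc} next to {path}")
    meta = json.loads(sc.read_text())
    data = tifffile.imread(path)
    data = data.reshape(tuple(meta["shape"])) if data.shape != tuple(meta["shape"]) else data
    ts = np.asarray(meta["timestamps_s"], dtype=float)
    if ts.size != data.shape[0]:
        raise ShapeMismatchError(
            f"sidecar has {ts.size} timestamps but stack has {data.shape[0]} frames"
        )
    if np.any(np.diff(ts) <= 0):
        raise TimestampError("sidecar timestamps are not strictly increasing")
    return IntensitySequence(
        values=np.asarray(data, dtype=float),
        timestamps_s=ts,
        voxel_size_um=tuple(meta["voxel_size_um"]),
    )


def write_map(path, values: np.ndarray, units: str, voxel_size_um, seed=None, extra_meta=None) -> Path:
    """Write a 3-D map (LIV, OCDS_l, product) as TIFF + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(values, dtype=np.float32)
    tifffile.imwrite(path, data, metadata={"axes": "ZYX"})
    meta = {
        "axes": "ZYX",
        "shape": list(data.shape),
        "dtype": "float32",
        "units": units,
        "voxel_size_um": list(voxel_size_um),
        "provenance": _provenance(seed, extra_meta),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_map(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise MissingSidecarError(f"no sidecar {sc} next to {path}")
    meta = json.loads(sc.read_text())
    data = tifffile.imread(path)
    if list(data.shape) != meta["shape"]:
        raise ShapeMismatchError(f"stack shape {data.shape} != sidecar {meta['shape']}")
    return np.asarray(data), meta


def write_mask(path, mask: np.ndarray, voxel_size_um, seed=None, extra_meta=None) -> Path:
    """Write a boolean mask as an 8-bit TIFF volume + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = (np.asarray(mask, dtype=bool).astype(np.uint8)) * np.uint8(255)
    tifffile.imwrite(path, data, metadata={"axes": "ZYX"})
    meta = {
        "axes": "ZYX",
        "shape": list(data.shape),
        "dtype": "uint8",
        "units": "binary",
        "voxel_size_um": list(voxel_size_um),
        "provenance": _provenance(seed, extra_meta),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path
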
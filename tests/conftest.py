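import numpy as np
import pytest

from spheroid_doct.config import PipelineConfig
from spheroid_doct.doct_metrics import IntensitySequence, compute_liv
from spheroid_doct.speckle_sim import make_spheroid_phantom, render_phantom_sequence

#: revisit timestamps of one B-scan location under the reference protocol
FRAME_TS_S = np.arange(32) * 0.2048


@pytest.fixture(scope="session")
def frame_ts():
    return FRAME_TS_S.copy()


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def random_sequence():
    """Small random dB sequence for oracle comparisons (8x8x8, 32 frames)."""
    rng = np.random.default_rng(123)
    values = rng.normal(20.0, 4.0, size=(32, 8, 8, 8))
    return IntensitySequence(values=values, timestamps_s=FRAME_TS_S, voxel_size_um=(5, 5, 5))


@pytest.fixture(scope="session")
def phantom_with_core():
    """Default spheroid phantom: viable shell, low-dynamics core, plate plane."""
    return make_spheroid_phantom(
        grid_shape=(48, 48, 48),
        sphere_radius_um=90.0,
        core_radius_um=50.0,
        plate_z_index=2,
        rng=11,
    )


@pytest.fixture(scope="session")
def rendered_phantom(phantom_with_core):
    """Rendered dB sequence + LIV map of the default phantom (shared)."""
    seq = render_phantom_sequence(phantom_with_core, FRAME_TS_S, n_phasors=16, rng=12)
    liv = compute_liv(seq)
    return phantom_with_core, seq, liv
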
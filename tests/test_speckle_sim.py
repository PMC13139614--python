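"""Simulator fidelity: ensemble autocorrelation against the closed form,
metric sensitivities, phantom geometry, scenario trajectories."""

import numpy as np
import pytest

from spheroid_doct.doct_metrics import IntensitySequence, compute_liv, to_db
from spheroid_doct.speckle_sim import (
    ScenarioParams,
    VoxelDynamics,
    make_spheroid_phantom,
    make_timelapse,
    render_location_sequence,
    render_phantom_sequence,
    simulate_field_sequence,
)

TS = np.arange(32) * 0.2048


def ensemble_g1(field, lag):
    """Normalized ensemble field autocorrelation at an integer frame lag."""
    num = (field[:-lag] * np.conj(field[lag:])).mean().real
    den = (np.abs(field) ** 2).mean()
    return num / den


class TestFieldSequence:
    def test_static_voxel_field_constant(self):
        fld = simulate_field_sequence(0.0, 500.0, 2.0, TS, n_phasors=16, rng=0)
        assert np.allclose(fld, fld[0], atol=1e-6)
        assert np.abs(fld[0]) ** 2 == pytest.approx(2.0, rel=1e-5)

    def test_mean_intensity_equals_backscatter(self):
        n = 20000
        fld = simulate_field_sequence(
            np.full(n, 0.7), np.full(n, 400.0), np.full(n, 3.0), TS, 16, rng=1
        )
        mean_i = (np.abs(fld) ** 2).mean()
        assert mean_i == pytest.approx(3.0, rel=0.02)

    def test_ensemble_g1_matches_closed_form(self):
        # g1(tau) = (1-f) + f exp(-tau/tau_c), checked within 3 SE at lag 1
        n = 20000
        f, tau = 0.5, 500.0
        fld = simulate_field_sequence(
            np.full(n, f), np.full(n, tau), np.ones(n), TS, 16, rng=2
        )
        expected = (1 - f) + f * np.exp(-204.8 / tau)
        num = (fld[:-1] * np.conj(fld[1:])).mean(axis=0).real
        den = (np.abs(fld) ** 2).mean(axis=0)
        g1_hat = num.mean() / den.mean()
        # delta-method SE of the ratio of means across independent voxels
        resid = num - expected * den
        se = resid.std() / (den.mean() * np.sqrt(n))
        assert abs(g1_hat - expected) < 3 * se

    def test_fast_full_dynamics_decorrelates_at_lag_one(self):
        # f=1, tau_c << frame interval: lag-1 intensity correlation ~ 0
        n = 20000
        fld = simulate_field_sequence(np.ones(n), np.full(n, 5.0), np.ones(n), TS, 16, rng=3)
        intensity = np.abs(fld) ** 2
        x = intensity - intensity.mean()  # ensemble mean: no per-voxel bias
        rho1 = (x[:-1] * x[1:]).mean() / (x * x).mean()
        assert abs(rho1) < 0.02

    def test_siegert_relation_for_full_dynamics(self):
        # fully dynamic speckle: intensity autocovariance ~ |g1|^2
        n = 30000
        tau = 600.0
        fld = simulate_field_sequence(np.ones(n), np.full(n, tau), np.ones(n), TS, 16, rng=4)
        intensity = np.abs(fld) ** 2
        x = intensity - intensity.mean()
        for lag in (1, 3):
            rho = (x[:-lag] * x[lag:]).mean() / (x * x).mean()
            expected = np.exp(-2 * lag * 204.8 / tau)
            assert rho == pytest.approx(expected, abs=0.03)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_field_sequence(1.2, 500.0, 1.0, TS, 16, rng=0)
        with pytest.raises(ValueError):
            simulate_field_sequence(0.5, 500.0, 1.0, [], 16, rng=0)
        with pytest.raises(ValueError):
            simulate_field_sequence(0.5, 500.0, 1.0, TS, n_phasors=4, rng=0)

    def test_liv_monotone_in_dynamic_fraction(self):
        # median dB-intensity variance rises with the dynamic fraction
        n = 10000
        medians = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            fld = simulate_field_sequence(
                np.full(n, f), np.full(n, 500.0), np.ones(n), TS, 16, rng=5
            )
            db = to_db(np.abs(fld) ** 2, 1e-3)
            medians.append(np.median(db.var(axis=0)))
        assert all(b > a for a, b in zip(medians, medians[1:]))


class TestRendering:
    def test_same_seed_bit_identical(self, phantom_with_core):
        a = render_phantom_sequence(phantom_with_core, TS[:8], rng=42)
        b = render_phantom_sequence(phantom_with_core, TS[:8], rng=42)
        assert np.array_equal(a.values, b.values)

    def test_different_seeds_differ(self, phantom_with_core):
        a = render_phantom_sequence(phantom_with_core, TS[:8], rng=1)
        b = render_phantom_sequence(phantom_with_core, TS[:8], rng=2)
        assert not np.array_equal(a.values, b.values)

    def test_zero_backscatter_zero_noise_clamps_at_floor(self):
        ph = make_spheroid_phantom(
            grid_shape=(8, 8, 8),
            sphere_radius_um=15.0,
            shell=VoxelDynamics(0.5, 500.0, 0.0),
            medium=VoxelDynamics(0.0, 1000.0, 0.0),
            noise_floor=0.0,
            rng=0,
        )
        seq = render_phantom_sequence(ph, TS[:4], rng=0, db_floor=1e-6)
        assert np.allclose(seq.values, -60.0)

    def test_plate_liv_below_shell_liv(self, rendered_phantom):
        # static bright plate: dimmer fluctuations than viable tissue in
        # >= 95% of plate voxels
        phantom, seq, liv = rendered_phantom
        shell_mask = phantom.sphere_mask & ~phantom.low_dynamics_mask
        shell_med = np.median(liv.values[shell_mask])
        frac = (liv.values[phantom.plate_mask] < shell_med).mean()
        assert frac >= 0.95

    def test_location_sequence_shape(self, phantom_with_core):
        seq = render_location_sequence(phantom_with_core, y_index=24, timestamps_s=TS[:4], rng=0)
        assert seq.values.shape == (4, 48, 1, 48)


class TestPhantomGeometry:
    def test_uniform_sphere_when_core_zero(self):
        ph = make_spheroid_phantom(grid_shape=(24, 24, 24), sphere_radius_um=40.0, rng=0)
        assert not ph.core_mask.any()
        inside = ph.dynamic_fraction[ph.sphere_mask]
        assert np.unique(inside).size == 1

    @pytest.mark.parametrize("radius_um", [50.0, 80.0, 100.0])
    def test_discretized_sphere_volume(self, radius_um):
        # voxel count x voxel volume within 10% of (4/3) pi r^3 for r >= 10 vox
        ph = make_spheroid_phantom(
            grid_shape=(48, 48, 48), voxel_size_um=(5, 5, 5), sphere_radius_um=radius_um, rng=0
        )
        vol = ph.sphere_mask.sum() * 125.0
        analytic = 4.0 / 3.0 * np.pi * radius_um**3
        assert vol == pytest.approx(analytic, rel=0.10)

    def test_core_larger_than_sphere_rejected(self):
        with pytest.raises(ValueError):
            make_spheroid_phantom(sphere_radius_um=50.0, core_radius_um=60.0)

    def test_sphere_must_fit_grid(self):
        with pytest.raises(ValueError):
            make_spheroid_phantom(grid_shape=(16, 16, 16), sphere_radius_um=200.0)

    def test_no_spots_without_spot_request(self):
        ph = make_spheroid_phantom(sphere_radius_um=80.0, core_radius_um=30.0, n_spots=0, rng=1)
        assert np.array_equal(ph.low_dynamics_mask, ph.core_mask)

    def test_plate_is_static_and_bright(self, phantom_with_core):
        ph = phantom_with_core
        assert np.all(ph.dynamic_fraction[ph.plate_mask] == 0.0)
        assert ph.backscatter[ph.plate_mask].min() > ph.backscatter[ph.sphere_mask].mean()


class TestTimelapse:
    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            make_timelapse("mystery_drug", [0, 4], seed=0)

    def test_control_zero_growth_is_static(self):
        p = ScenarioParams(growth_rate_per_hr=0.0)
        tl = make_timelapse("control", [0, 10, 20], params=p, seed=0)
        masks = [ph.sphere_mask for _, ph in tl.frames]
        assert np.array_equal(masks[0], masks[1]) and np.array_equal(masks[0], masks[2])

    def test_control_radius_grows_monotonically(self):
        tl = make_timelapse("control", [0, 20, 40, 60], seed=0)
        radii = [ph.sphere_radius_um for _, ph in tl.frames]
        assert all(b > a for a, b in zip(radii, radii[1:]))

    def test_dox_core_expands_after_onset(self):
        p = ScenarioParams(onset_hr=32.0)
        tl = make_timelapse("dox_like", [0, 32, 48, 64, 100], params=p, seed=0)
        cores = {t: ph.core_radius_um for t, ph in tl.frames}
        assert cores[0] == cores[32] == 0.0
        assert cores[48] < cores[64] < cores[100]
        radii = {t: ph.sphere_radius_um for t, ph in tl.frames}
        assert radii[100] == pytest.approx(radii[48])  # growth suppressed

    def test_tam_growth_slowed_dynamics_unchanged(self):
        p = ScenarioParams(onset_hr=32.0)
        ctrl = make_timelapse("control", [100], params=p, seed=0)
        tam = make_timelapse("tam_like", [100], params=p, seed=0)
        assert tam.frames[0][1].sphere_radius_um < ctrl.frames[0][1].sphere_radius_um
        assert not tam.frames[0][1].low_dynamics_mask.any()

    def test_ptx_spot_count_non_decreasing(self):
        p = ScenarioParams(onset_hr=32.0, spot_rate_per_hr=0.25)
        tl = make_timelapse("ptx_like", [0, 40, 60, 80, 100], params=p, seed=3)
        low_volumes = [ph.low_dynamics_mask.sum() for _, ph in tl.frames]
        assert low_volumes[0] == 0
        assert all(b >= a for a, b in zip(low_volumes, low_volumes[1:]))
        assert low_volumes[-1] > 0
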
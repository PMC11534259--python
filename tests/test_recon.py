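"""Acquisition and regridding reconstruction: trajectory geometry, forward
models against exact and analytic oracles, and image-domain properties."""

import numpy as np
import pytest

from natsc.core import GridMeta, ScalarVolume
from natsc.recon import (
    SequenceParams,
    make_trajectory,
    reconstruct,
    simulate_acquisition,
    steady_state_signal,
)


def _ball_volume(radius_mm, n, spacing, center_offset=(0, 0, 0), value=1.0):
    meta = GridMeta(shape=(n, n, n), spacing=(spacing,) * 3)
    x, y, z = meta.coordinate_arrays()
    c = np.array(meta.fov_mm) / 2 + np.asarray(center_offset, float)
    mask = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= radius_mm**2
    return ScalarVolume(mask.astype(float) * value, meta), meta, c


def _analytic_ball_ft(kpts, radius_mm, center, fov_center):
    k = np.linalg.norm(kpts, axis=1)
    kr = 2.0 * np.pi * k * radius_mm
    vol = 4.0 / 3.0 * np.pi * radius_mm**3
    mag = np.where(
        kr > 1e-9,
        vol * 3.0 * (np.sin(kr) - kr * np.cos(kr)) / np.maximum(kr, 1e-12) ** 3,
        vol,
    )
    shift = np.asarray(center) - np.asarray(fov_center)
    return mag * np.exp(-2j * np.pi * (kpts @ shift))


class TestTrajectory:
    def test_max_k_is_nyquist_of_nominal_resolution(self):
        traj = make_trajectory(SequenceParams(n_spokes=500, n_samples=128))
        kmax = np.linalg.norm(traj.flat_traj(), axis=1).max()
        assert kmax == pytest.approx(1.0 / (2.0 * 4.0), rel=0.01)

    def test_spoke_directions_quasi_uniform(self):
        n = 2000
        traj = make_trajectory(SequenceParams(n_spokes=n, n_samples=8))
        tips = traj.trajectory[:, -1, :]
        dirs = tips / np.linalg.norm(tips, axis=1, keepdims=True)
        dots = dirs @ dirs.T
        np.fill_diagonal(dots, -1.0)
        nn_angle = np.arccos(np.clip(dots.max(axis=1), -1, 1))
        expected = np.sqrt(4.0 * np.pi / n)
        assert abs(nn_angle.mean() - expected) / expected < 0.20

    def test_dcf_constant_on_uniform_density_segment(self):
        params = SequenceParams(n_spokes=10, n_samples=384)
        traj = make_trajectory(params)
        k = np.linalg.norm(traj.trajectory[0], axis=1)
        k0 = params.ramp_fraction * params.kmax
        interior = (k > 1.3 * k0) & (k < 0.98 * params.kmax)
        dcf = traj.dcf[0][interior]
        assert np.ptp(dcf) / dcf.mean() < 1e-6

    def test_dcf_grows_as_k_squared_on_ramp(self):
        params = SequenceParams(n_spokes=10, n_samples=2048)
        traj = make_trajectory(params)
        k = np.linalg.norm(traj.trajectory[0], axis=1)
        k0 = params.ramp_fraction * params.kmax
        on_ramp = (k > 0.2 * k0) & (k < 0.9 * k0)
        ratio = traj.dcf[0][on_ramp] / k[on_ramp] ** 2
        assert np.ptp(ratio) / ratio.mean() < 0.02


class TestSteadyStateSignal:
    @pytest.mark.parametrize(
        "t1,t2s,te,expected_ratio",
        [
            (1e-6, 1e12, 0.4, 1.0),  # full relaxation, no decay
            (50.0, 1e12, 0.0, 1.0 - np.exp(-2.0)),  # ≈ 0.864665
            (35.0, 4.0, 0.4, (1.0 - np.exp(-100.0 / 35.0)) * np.exp(-0.1)),
        ],
    )
    def test_closed_form_weighting(self, t1, t2s, te, expected_ratio):
        meta = GridMeta(shape=(4, 4, 4), spacing=(2.0,) * 3)
        tsc = ScalarVolume(np.full(meta.shape, 50.0), meta)
        mk = lambda v: ScalarVolume(np.full(meta.shape, v), meta)  # noqa: E731
        params = SequenceParams(te_ms=te)
        sig = steady_state_signal(tsc, mk(t1), mk(t2s), params)
        assert sig.data.flat[0] / 50.0 == pytest.approx(expected_ratio, rel=1e-6)

    def test_nonpositive_relaxation_rejected(self):
        meta = GridMeta(shape=(4, 4, 4), spacing=(2.0,) * 3)
        tsc = ScalarVolume(np.ones(meta.shape), meta)
        bad = ScalarVolume(np.zeros(meta.shape), meta)
        good = ScalarVolume(np.ones(meta.shape), meta)
        with pytest.raises(ValueError, match="relaxation"):
            steady_state_signal(tsc, bad, good, SequenceParams())


class TestForwardModel:
    def test_zero_signal_noise_free_gives_exact_zeros(self):
        vol, *_ = _ball_volume(6.0, 16, 2.0, value=0.0)
        params = SequenceParams(n_spokes=100, n_samples=32, fov_mm=32.0)
        ks = simulate_acquisition(vol, make_trajectory(params), noise_sd=0.0)
        assert np.all(ks.flat_samples() == 0)

    def test_fast_nufft_agrees_with_exact_nudft(self):
        vol, *_ = _ball_volume(8.0, 24, 2.0)
        params = SequenceParams(n_spokes=300, n_samples=48, fov_mm=48.0)
        traj = make_trajectory(params)
        fast = simulate_acquisition(vol, traj, method="nufft").flat_samples()
        exact = simulate_acquisition(vol, traj, method="nudft").flat_samples()
        rms = np.sqrt(np.mean(np.abs(fast - exact) ** 2) / np.mean(np.abs(exact) ** 2))
        assert rms < 0.01

    def test_forward_matches_analytic_ball_transform(self):
        vol, meta, center = _ball_volume(10.0, 48, 1.0)
        params = SequenceParams(n_spokes=800, n_samples=96, fov_mm=48.0)
        traj = make_trajectory(params)
        ks = simulate_acquisition(vol, traj, method="nufft")
        ref = _analytic_ball_ft(ks.flat_traj(), 10.0, center, ks.fov_center_mm)
        s = ks.flat_samples()
        rms = np.sqrt(np.mean(np.abs(s - ref) ** 2) / np.mean(np.abs(ref) ** 2))
        assert rms < 0.02

    def test_noise_deterministic_given_seed(self):
        vol, *_ = _ball_volume(6.0, 16, 2.0)
        params = SequenceParams(n_spokes=80, n_samples=32, fov_mm=32.0)
        traj = make_trajectory(params)
        a = simulate_acquisition(vol, traj, noise_sd=2.0, seed=42).flat_samples()
        b = simulate_acquisition(vol, traj, noise_sd=2.0, seed=42).flat_samples()
        c = simulate_acquisition(vol, traj, noise_sd=2.0, seed=43).flat_samples()
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_coarser_grid_than_nominal_resolution_rejected(self):
        meta = GridMeta(shape=(8, 8, 8), spacing=(8.0,) * 3)
        vol = ScalarVolume(np.ones(meta.shape), meta)
        params = SequenceParams(n_spokes=10, n_samples=8)
        with pytest.raises(ValueError, match="coarser"):
            simulate_acquisition(vol, make_trajectory(params))


class TestReconstruct:
    @pytest.fixture(scope="class")
    def ball_recon(self):
        vol, meta, center = _ball_volume(10.0, 48, 1.0)
        params = SequenceParams(n_spokes=2000, n_samples=96, fov_mm=48.0)
        ks = simulate_acquisition(vol, make_trajectory(params))
        return reconstruct(ks), ks, center

    def test_ball_interior_amplitude_and_background(self, ball_recon):
        img, ks, center = ball_recon
        x, y, z = img.meta.coordinate_arrays()
        c = np.asarray(ks.fov_center_mm)
        r = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
        interior = img.data[r < 8.0].mean()  # one apparent voxel inside
        background = img.data[(r > 16.0) & (r < 22.0)].mean()
        assert abs(interior - 1.0) < 0.05
        assert background < 0.05 * interior

    def test_output_grid_is_zero_filled_apparent_resolution(self, ball_recon):
        img, ks, _ = ball_recon
        params = ks.params
        expected = tuple(
            int(params.zero_fill_factor * round(f / params.nominal_res_mm))
            for f in ks.fov_mm
        )
        assert img.data.shape == expected
        assert img.meta.spacing == pytest.approx((2.0, 2.0, 2.0))

    def test_two_balls_12mm_apart_are_resolved(self):
        meta = GridMeta(shape=(64, 64, 64), spacing=(1.0,) * 3)
        x, y, z = meta.coordinate_arrays()
        c = np.array(meta.fov_mm) / 2
        b1 = (x - (c[0] - 6)) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= 16.0
        b2 = (x - (c[0] + 6)) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= 16.0
        vol = ScalarVolume((b1 | b2).astype(float), meta)
        params = SequenceParams(n_spokes=1500, n_samples=96, fov_mm=64.0)
        ks = simulate_acquisition(vol, make_trajectory(params))
        img = reconstruct(ks)
        m = img.data.shape[1] // 2
        prof = img.data[:, m, m]
        xi = img.meta.coordinate_arrays()[0][:, m, m]
        cen = ks.fov_center_mm[0]
        peak1 = prof[np.abs(xi - (cen - 6)).argmin()]
        peak2 = prof[np.abs(xi - (cen + 6)).argmin()]
        trough = prof[np.abs(xi - cen).argmin()]
        assert trough < 0.8 * min(peak1, peak2)

    def test_complex_reconstruction_is_linear(self):
        vol1, meta, _ = _ball_volume(8.0, 24, 2.0)
        vol2 = ScalarVolume(
            np.roll(vol1.data, 4, axis=0) * 2.0, meta
        )  # shifted, scaled copy
        params = SequenceParams(n_spokes=300, n_samples=48, fov_mm=48.0)
        traj = make_trajectory(params)
        ks1 = simulate_acquisition(vol1, traj)
        ks2 = simulate_acquisition(vol2, traj)
        a, b = 2.0, -0.7
        from dataclasses import replace

        ks_mix = replace(ks1, samples=a * ks1.samples + b * ks2.samples)
        mix = reconstruct(ks_mix, return_complex=True).data
        lin = a * reconstruct(ks1, return_complex=True).data + b * reconstruct(
            ks2, return_complex=True
        ).data
        assert np.allclose(mix, lin, atol=1e-9 * np.abs(lin).max())

    def test_noise_propagation_scales_linearly(self):
        vol, meta, _ = _ball_volume(12.0, 32, 2.0)
        params = SequenceParams(n_spokes=500, n_samples=64, fov_mm=64.0)
        traj = make_trajectory(params)
        ks0 = simulate_acquisition(vol, traj)
        base = reconstruct(ks0).data
        rms = np.sqrt(np.mean(np.abs(ks0.flat_samples()) ** 2))

        def noise_level(frac, seeds=(1, 2, 3)):
            out = []
            for s in seeds:
                ksn = simulate_acquisition(vol, traj, noise_sd=frac * rms, seed=s)
                out.append((reconstruct(ksn).data - base).std())
            return np.mean(out)

        ratio = noise_level(0.02) / noise_level(0.01)
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_missing_samples_raises(self):
        traj = make_trajectory(SequenceParams(n_spokes=10, n_samples=8))
        with pytest.raises(ValueError, match="samples"):
            reconstruct(traj)
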
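"""Equipartition sampling, sectioning, rendering and rigid-body simulation."""

import numpy as np
import pytest

from flickerspec import (
    ContourConfig,
    ModelParams,
    OpticsModel,
    RigidConfig,
    aggregate_modes,
    decompose_contour,
    equatorial_contour,
    extract_contour,
    model_spectrum,
    render_frame,
    sample_equilibrium_modes,
    simulate_droplet_video,
    simulate_rigid_rotation,
    zplane_robustness,
)
from flickerspec.synthetic_data import mode_variance
from conftest import PIXEL_SIZE_UM, frame_center, make_contour

PARAMS = ModelParams(kappa=2.0, sigma_bar=50.0, radius=0.8)


class TestSampleEquilibriumModes:
    def test_no_volume_or_translation_modes(self):
        shape = sample_equilibrium_modes(PARAMS, l_sim=20, rng_seed=0)
        assert shape.l_index.min() == 2
        assert np.all(np.abs(shape.m_index) <= shape.l_index)

    @pytest.mark.parametrize("l,m", [(2, 0), (5, 3)])
    def test_sampled_variance_matches_equipartition(self, l, m):
        rng = np.random.default_rng(42)
        ref = sample_equilibrium_modes(PARAMS, l_sim=15, rng_seed=0)
        idx = np.flatnonzero((ref.l_index == l) & (ref.m_index == m))[0]
        draws = np.array(
            [
                sample_equilibrium_modes(PARAMS, l_sim=15, rng_seed=rng).amplitudes[idx]
                for _ in range(4000)
            ]
        )
        var = mode_variance(PARAMS, np.array([l]))[0]
        se = var * np.sqrt(2 / draws.size)
        assert abs(draws.var() - var) < 3 * se

    def test_doubling_kappa_halves_variance(self):
        v1 = mode_variance(PARAMS, np.arange(2, 20))
        v2 = mode_variance(
            ModelParams(kappa=4.0, sigma_bar=50.0, radius=0.8), np.arange(2, 20)
        )
        np.testing.assert_allclose(v1, 2 * v2, rtol=1e-14)

    def test_requires_l_sim_at_least_15(self):
        with pytest.raises(ValueError):
            sample_equilibrium_modes(PARAMS, l_sim=10, rng_seed=0)


class TestEquatorialContour:
    def test_zero_amplitudes_give_perfect_circle(self):
        shape = sample_equilibrium_modes(PARAMS, l_sim=15, rng_seed=0)
        shape.amplitudes[:] = 0.0
        contour = equatorial_contour(shape)
        np.testing.assert_allclose(contour.radii, PARAMS.radius, rtol=1e-14)

    def test_pure_20_mode_is_invisible_on_the_equator(self):
        """Y_20 is phi-independent at theta = pi/2: no q >= 1 contour power."""
        shape = sample_equilibrium_modes(PARAMS, l_sim=15, rng_seed=0)
        shape.amplitudes[:] = 0.0
        shape.amplitudes[(shape.l_index == 2) & (shape.m_index == 0)] = 0.05
        contour = equatorial_contour(shape)
        assert np.ptp(contour.radii) < 1e-12
        amps = decompose_contour(contour)
        np.testing.assert_allclose(np.abs(amps.upsilon), 0.0, atol=1e-14)

    def test_apparent_radius_shrinks_off_equator(self):
        shape = sample_equilibrium_modes(PARAMS, l_sim=15, rng_seed=1)
        shape.amplitudes[:] = 0.0
        means = [
            equatorial_contour(shape, tilt_deg=t).mean_radius for t in [0, 10, 20, 30]
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_rejects_vertical_planes(self):
        shape = sample_equilibrium_modes(PARAMS, l_sim=15, rng_seed=0)
        with pytest.raises(ValueError):
            equatorial_contour(shape, tilt_deg=95.0)


class TestRenderFrame:
    def test_sharp_noiseless_disc_has_circle_area(self, circle_contour):
        optics = OpticsModel(psf_sigma=0.0, snr=5.0, pixel_size=PIXEL_SIZE_UM)
        frame = render_frame(circle_contour, optics, noise=False)
        area = np.sum(frame.pixels > 0.6)
        assert area == pytest.approx(np.pi * 12.0**2, rel=0.03)

    def test_measured_snr_matches_configuration(self, circle_contour, paper_optics):
        frame = render_frame(circle_contour, paper_optics, rng_seed=8)
        cy, cx = frame_center(frame)
        rows, cols = np.indices(frame.pixels.shape)
        r = np.hypot(rows - cy, cols - cx)
        fg = frame.pixels[r < 8].mean()
        bg = frame.pixels[r > 18]
        snr = (fg - bg.mean()) / bg.std()
        assert snr == pytest.approx(5.0, rel=0.1)

    def test_round_trip_time_average_within_0_1_px(self, circle_contour, paper_optics):
        """The mean extracted boundary over repeated noisy renderings stays
        within 0.1 px RMS of a constant circle (bias removed: it is uniform
        and cancels in every fluctuation mode)."""
        f0 = render_frame(circle_contour, paper_optics, rng_seed=0)
        center = frame_center(f0)
        extracted = []
        for s in range(60):
            frame = render_frame(circle_contour, paper_optics, rng_seed=100 + s)
            contour = extract_contour(frame, center, scale=12.0)
            if contour.valid:
                extracted.append(contour.radii)
        assert len(extracted) >= 55
        mean_profile = np.mean(extracted, axis=0)
        rms = np.sqrt(np.mean((mean_profile - mean_profile.mean()) ** 2))
        assert rms < 0.1

    def test_reproducible_from_seed(self, circle_contour, paper_optics):
        a = render_frame(circle_contour, paper_optics, rng_seed=5)
        b = render_frame(circle_contour, paper_optics, rng_seed=5)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_rejects_contour_larger_than_frame(self, circle_contour, paper_optics):
        with pytest.raises(ValueError):
            render_frame(circle_contour, paper_optics, frame_shape=(20, 20))


class TestSimulateDropletVideo:
    def test_frame_count_and_determinism(self, paper_optics):
        a = simulate_droplet_video(PARAMS, paper_optics, 5, rng_seed=3, l_sim=20)
        b = simulate_droplet_video(PARAMS, paper_optics, 5, rng_seed=3, l_sim=20)
        assert a.frames.shape[0] == 5
        np.testing.assert_array_equal(a.frames, b.frames)
        assert a.truth["kappa"] == 2.0

    def test_ground_truth_contours_match_model_spectrum(self, paper_optics):
        video = simulate_droplet_video(PARAMS, paper_optics, 600, rng_seed=4, l_sim=40)
        amps = [decompose_contour(c) for c in video.contours]
        stats = aggregate_modes(amps)
        params40 = ModelParams(kappa=2.0, sigma_bar=50.0, radius=0.8, l_max=40)
        model = model_spectrum(params40).power
        ups = np.stack([a.upsilon for a in amps])[:, 1:]
        se = (np.abs(ups) ** 2).std(axis=0) / np.sqrt(len(amps))
        assert np.all(np.abs(stats.F2[1:] - model) < 3.5 * se + model * 0.01)

    def test_fixed_shape_video_has_static_contours(self, paper_optics):
        video = simulate_droplet_video(
            PARAMS, paper_optics, 4, rng_seed=5, l_sim=20, fixed_shape=True
        )
        for c in video.contours[1:]:
            np.testing.assert_array_equal(c.radii, video.contours[0].radii)


class TestSimulateRigidRotation:
    def test_produces_requested_rotations(self):
        contours = simulate_rigid_rotation(RigidConfig(n_rotations=100, seed=1))
        assert len(contours) == 100
        assert all(c.radii.size == 400 for c in contours)

    def test_frozen_rotation_limit_has_no_fluctuation_power(self):
        """beta -> very negative means no rotation: all contours coincide
        and the corrected power F2 vanishes."""
        contours = simulate_rigid_rotation(RigidConfig(beta=-30.0, seed=2))
        amps = [decompose_contour(c) for c in contours]
        stats = aggregate_modes(amps)
        np.testing.assert_allclose(stats.F2, 0.0, atol=1e-12)
        assert np.any(stats.C2 > 0)

    def test_reproducible_from_seed(self):
        a = simulate_rigid_rotation(RigidConfig(seed=7, n_rotations=10))
        b = simulate_rigid_rotation(RigidConfig(seed=7, n_rotations=10))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.radii, cb.radii)


class TestZPlaneRobustness:
    def test_tilt_zero_is_the_baseline_and_radius_shrinks(self):
        df = zplane_robustness(PARAMS, [0, 10, 20], 400, rng_seed=3, l_sim=30)
        base = df[df.tilt_deg == 0].iloc[0]
        assert base.rel_dev_kappa == 0.0
        assert base.rel_dev_sigma == 0.0

    def test_small_tilts_barely_move_the_fit(self):
        """<= 20 deg off-equator shifts (sigma, kappa) by far less than the
        width of a typical population band (factor ~2.4)."""
        df = zplane_robustness(PARAMS, [0, 10, 20], 600, rng_seed=5, l_sim=30)
        assert np.all(np.abs(df.rel_dev_kappa) < 0.4)
        assert np.all(np.abs(df.rel_dev_sigma) < 0.4)

    def test_rejects_large_tilts(self):
        with pytest.raises(ValueError):
            zplane_robustness(PARAMS, [0, 40], 100, rng_seed=0)
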
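"""Detection, flood fill, gradient stencil, ray extraction and tracking."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flickerspec import (
    Contour,
    ContourConfig,
    DetectionConfig,
    GranuleSeed,
    ImageFrame,
    OpticsModel,
    detect_granules,
    estimate_extent,
    extract_contour,
    gradient_field,
    render_frame,
    track_granules,
    validate_contour,
)
from conftest import PIXEL_SIZE_UM, frame_center, make_contour


def _disc_frame(radius_px=12.0, snr=5.0, seed=0, noise=True, psf=1.3):
    optics = OpticsModel(psf_sigma=psf, snr=snr, pixel_size=PIXEL_SIZE_UM)
    contour = make_contour(np.full(400, radius_px))
    return render_frame(contour, optics, rng_seed=seed, noise=noise)


class TestDetectGranules:
    def test_single_disc_found_within_one_pixel(self):
        frame = _disc_frame(seed=3)
        seeds = detect_granules(frame)
        assert len(seeds) == 1
        cy, cx = frame_center(frame)
        assert np.hypot(seeds[0].center[0] - cy, seeds[0].center[1] - cx) < 1.0
        assert seeds[0].scale > 0

    def test_pure_noise_frame_is_empty(self):
        rng = np.random.default_rng(0)
        frame = ImageFrame(pixels=np.abs(rng.normal(0.2, 0.04, (64, 64))))
        assert detect_granules(frame) == []

    def test_blank_frame_is_empty(self):
        assert detect_granules(ImageFrame(pixels=np.zeros((64, 64)))) == []

    def test_two_discs_give_two_seeds(self):
        one = _disc_frame(radius_px=8.0, seed=1).pixels
        h = one.shape[0]
        canvas = np.full((h, h + 30), 0.2 * one.max())
        canvas[:, :h] = np.maximum(canvas[:, :h], one)
        canvas[:, 30:] = np.maximum(canvas[:, 30:], one)
        seeds = detect_granules(ImageFrame(pixels=canvas))
        assert len(seeds) == 2
        cols = sorted(s.center[1] for s in seeds)
        assert cols[1] - cols[0] == pytest.approx(30, abs=2)

    def test_rejects_tiny_frames(self):
        with pytest.raises(ValueError):
            detect_granules(ImageFrame(pixels=np.zeros((16, 16))))


class TestEstimateExtent:
    def test_uniform_disc_mask_recovers_disc(self):
        img = np.zeros((64, 64))
        rows, cols = np.indices(img.shape)
        disc = (rows - 32) ** 2 + (cols - 32) ** 2 <= 10**2
        img[disc] = 1.0
        seed = GranuleSeed(center=(32.0, 32.0), scale=10.0, response=1.0)
        mask = estimate_extent(ImageFrame(pixels=img), seed)
        assert mask.sum() == pytest.approx(np.pi * 100, rel=0.1)
        assert np.array_equal(mask, disc)

    def test_small_disc_rejected_by_area_floor(self):
        # radius 5 px -> area ~79 < 100
        img = np.zeros((64, 64))
        rows, cols = np.indices(img.shape)
        img[(rows - 32) ** 2 + (cols - 32) ** 2 <= 5**2] = 1.0
        seed = GranuleSeed(center=(32.0, 32.0), scale=5.0, response=1.0)
        assert not estimate_extent(ImageFrame(pixels=img), seed).any()

    def test_seed_below_threshold_gives_empty_mask(self):
        img = np.zeros((64, 64))
        img[10, 10] = 1.0  # maximum far from seed
        seed = GranuleSeed(center=(32.0, 32.0), scale=10.0, response=1.0)
        assert not estimate_extent(ImageFrame(pixels=img), seed).any()

    def test_local_reference_tolerates_brighter_neighbours(self):
        img = np.zeros((64, 128))
        rows, cols = np.indices(img.shape)
        img[(rows - 32) ** 2 + (cols - 32) ** 2 <= 10**2] = 0.4  # dim granule
        img[(rows - 32) ** 2 + (cols - 96) ** 2 <= 10**2] = 1.0  # bright cell
        seed = GranuleSeed(center=(32.0, 32.0), scale=10.0, response=1.0)
        assert not estimate_extent(ImageFrame(pixels=img), seed).any()
        assert estimate_extent(ImageFrame(pixels=img), seed, local_max=True).sum() > 100


class TestGradientField:
    def test_exact_on_linear_field(self):
        rows, cols = np.indices((32, 32), dtype=float)
        grad, valid = gradient_field(ImageFrame(pixels=3 * rows + 2 * cols))
        np.testing.assert_allclose(grad[0][valid], 3.0, atol=1e-12)
        np.testing.assert_allclose(grad[1][valid], 2.0, atol=1e-12)

    def test_exact_on_random_quartics(self):
        """The five-point stencil differentiates quartics exactly."""
        rng = np.random.default_rng(7)
        x = np.arange(40, dtype=float)
        rows, cols = np.meshgrid(x, x, indexing="ij")
        c = rng.normal(size=5)
        img = sum(c[k] * rows**k for k in range(5))
        deriv = sum(k * c[k] * rows ** (k - 1) for k in range(1, 5))
        grad, valid = gradient_field(ImageFrame(pixels=img))
        np.testing.assert_allclose(grad[0][valid], deriv[valid], rtol=1e-9)

    def test_fourth_order_on_gaussian_blob(self):
        """Error shrinks ~16x when the grid is refined 2x (O(h^4))."""
        def err(h):
            x = np.arange(-6, 6 + h / 2, h)
            rows, cols = np.meshgrid(x, x, indexing="ij")
            img = np.exp(-(rows**2 + cols**2) / 2)
            grad, valid = gradient_field(ImageFrame(pixels=img))
            truth = -rows * img
            return np.max(np.abs(grad[0] / h - truth)[valid])

        ratio = err(0.2) / err(0.1)
        assert ratio == pytest.approx(16.0, rel=0.3)

    def test_rejects_sub_stencil_frames(self):
        with pytest.raises(ValueError):
            gradient_field(ImageFrame(pixels=np.zeros((4, 10))))


class TestExtractContour:
    def test_clean_circle_recovered_below_0_05_px_rms(self):
        frame = _disc_frame(noise=False, psf=1.0)
        cfg = ContourConfig(presmooth_sigma=0.0)
        contour = extract_contour(frame, frame_center(frame), scale=12.0, config=cfg)
        assert contour.valid
        rms = np.sqrt(np.mean((contour.radii - 12.0) ** 2))
        assert rms < 0.05

    def test_always_400_evenly_spaced_angles(self):
        frame = _disc_frame(seed=5)
        contour = extract_contour(frame, frame_center(frame), scale=12.0)
        assert contour.angles.size == 400
        np.testing.assert_allclose(np.diff(contour.angles), 2 * np.pi / 400)

    def test_noiseless_mode_recovery_with_psf_attenuation(self):
        """A q=3 ripple of 0.3 px survives extraction with ~12% PSF loss."""
        angles = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        contour_in = make_contour(12.0 + 0.3 * np.cos(3 * angles))
        optics = OpticsModel(psf_sigma=1.3, snr=5.0, pixel_size=PIXEL_SIZE_UM)
        frame = render_frame(contour_in, optics, noise=False)
        out = extract_contour(frame, frame_center(frame), scale=12.0)
        spec = np.abs(np.fft.rfft(out.radii - out.radii.mean())) / 400 * 2
        assert 0.22 < spec[3] < 0.32

    def test_center_margin_enforced(self):
        frame = _disc_frame()
        with pytest.raises(ValueError):
            extract_contour(frame, (1.0, 1.0), scale=12.0)


class TestValidateContour:
    @given(st.floats(min_value=1e-3, max_value=10.0))
    def test_circle_passes_any_positive_threshold(self, thr):
        contour = make_contour(np.full(400, 12.0))
        assert validate_contour(contour, jump_threshold=thr).ok

    def test_single_large_jump_fails(self):
        radii = np.full(400, 12.0)
        radii[100] = 12.0 + 0.5 * 12.0
        contour = make_contour(radii)
        result = validate_contour(contour)
        assert not result.ok
        assert 99 in result.bad_indices or 100 in result.bad_indices
        assert not contour.valid

    def test_invalid_ray_fails(self):
        contour = make_contour(np.full(400, 12.0))
        contour.ray_valid[7] = False
        assert not validate_contour(contour).ok

    def test_merged_discs_overhang_fails(self):
        """Two merging discs leave a waist the radial function cannot follow."""
        img = np.zeros((80, 100))
        rows, cols = np.indices(img.shape)
        img[(rows - 40) ** 2 + (cols - 38) ** 2 <= 14**2] = 1.0
        img[(rows - 40) ** 2 + (cols - 58) ** 2 <= 11**2] = 1.0
        frame = ImageFrame(pixels=img)
        contour = extract_contour(frame, (40.0, 38.0), scale=14.0)
        assert not validate_contour(contour).ok

    def test_rejects_non_positive_threshold(self):
        with pytest.raises(ValueError):
            validate_contour(make_contour(np.full(400, 12.0)), jump_threshold=0.0)


def _seed(r, c, scale=10.0):
    return GranuleSeed(center=(r, c), scale=scale, response=1.0)


class TestTrackGranules:
    def test_static_disc_single_track(self):
        detections = [[_seed(30.0, 30.0)] for _ in range(100)]
        tracks = track_granules(detections)
        assert len(tracks) == 1
        assert tracks[0].length == 100

    def test_slow_drift_stays_linked(self):
        detections = [[_seed(30.0, 30.0 + 0.2 * i)] for i in range(100)]
        tracks = track_granules(detections)
        assert len(tracks) == 1
        assert tracks[0].length == 100

    def test_appearing_granule_starts_new_track(self):
        detections = [
            [_seed(30.0, 30.0)] if i < 50 else [_seed(30.0, 30.0), _seed(60.0, 60.0)]
            for i in range(100)
        ]
        tracks = track_granules(detections)
        assert len(tracks) == 2
        assert sorted(t.length for t in tracks) == [50, 100]

    def test_track_dies_after_five_missed_frames(self):
        detections = [[_seed(30.0, 30.0)]] * 10 + [[]] * 6 + [[_seed(30.0, 30.0)]] * 5
        tracks = track_granules(detections)
        assert len(tracks) == 2

    def test_gap_shorter_than_memory_is_bridged(self):
        detections = [[_seed(30.0, 30.0)]] * 10 + [[]] * 4 + [[_seed(30.0, 30.0)]] * 5
        tracks = track_granules(detections)
        assert len(tracks) == 1

    def test_permutation_invariant_within_frame(self):
        a, b = _seed(20.0, 20.0), _seed(50.0, 50.0)
        fwd = track_granules([[a, b]] * 20)
        rev = track_granules([[b, a]] * 20)
        key = lambda tracks: sorted(
            (t.seeds[0].center, t.length) for t in tracks
        )
        assert key(fwd) == key(rev)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            track_granules([[_seed(1.0, 1.0)]])
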
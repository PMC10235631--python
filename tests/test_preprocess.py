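import numpy as np
import pytest
from scipy import ndimage

from osteotex.errors import (
    CalibrationError,
    DataError,
    DegeneratePolygonError,
    ParameterError,
)
from osteotex.image import GrayImage
from osteotex.preprocess import (
    GeometryCalibration,
    estimate_sod,
    flat_field_correct,
    normalize_magnification,
    reduce_haze,
    roi_from_corners,
    stretch_window,
)


def _img(pixels):
    return GrayImage(np.asarray(pixels, dtype=float))


class TestFlatField:
    def test_constant_image_unchanged(self):
        img = _img(np.full((32, 32), 0.4))
        out = flat_field_correct(img, sigma=5.0)
        np.testing.assert_allclose(out.pixels, 0.4)

    def test_mean_preserved_within_1pct(self, rng):
        pix = np.clip(0.5 + 0.1 * rng.standard_normal((512, 512)), 0, 1)
        img = _img(pix)
        out = flat_field_correct(img, sigma=20.0)
        assert abs(out.pixels.mean() - img.pixels.mean()) <= 0.01 * img.pixels.mean()

    def test_removes_low_frequency_ramp(self, rng):
        texture = 0.1 * rng.standard_normal((256, 256))
        ramp = np.linspace(0.3, 0.7, 256)[None, :] * np.ones((256, 1))
        img = _img(np.clip(0.3 + texture, 0, 1) * ramp / ramp.mean())
        img = _img(np.clip(img.pixels, 0.01, 1))
        corrected = flat_field_correct(img, sigma=40.0)

        def corr(a):
            return np.corrcoef(a.ravel(), texture.ravel())[0, 1]

        assert corr(corrected.pixels) > corr(img.pixels)

    def test_idempotent_on_fixed_point(self):
        # constant images are exact fixed points of the division correction
        img = _img(np.full((64, 64), 0.37))
        once = flat_field_correct(img, sigma=30.0)
        twice = flat_field_correct(once, sigma=30.0)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-6)

    def test_repeat_application_contracts(self):
        # for non-fixed-point inputs, a second pass moves the image less
        # than the first did (the correction is only asymptotically idempotent)
        yy, xx = np.mgrid[0:64, 0:64] / 64.0
        background = 0.4 + 0.2 * np.sin(xx * 2) * np.cos(yy)
        img = _img(background)
        once = flat_field_correct(img, sigma=30.0)
        twice = flat_field_correct(once, sigma=30.0)
        d1 = np.abs(once.pixels - img.pixels).mean()
        d2 = np.abs(twice.pixels - once.pixels).mean()
        assert d2 < d1

    def test_sigma_must_be_positive(self):
        with pytest.raises(ParameterError):
            flat_field_correct(_img(np.full((20, 20), 0.5)), sigma=0.0)


class TestReduceHaze:
    def test_amount_zero_is_identity(self, textured_gray):
        out = reduce_haze(textured_gray, 0.0)
        np.testing.assert_array_equal(out.pixels, textured_gray.pixels)

    @pytest.mark.parametrize("amount", [0.05, 0.5, 1.0])
    def test_constant_image_fixed_point(self, amount):
        img = _img(np.full((32, 32), 0.6))
        out = reduce_haze(img, amount)
        np.testing.assert_allclose(out.pixels, 0.6, atol=1e-12)

    def test_restores_contrast_on_hazy_fixture(self, rng):
        texture = np.clip(0.5 + 0.15 * rng.standard_normal((128, 128)), 0, 1)
        hazy = _img(np.clip(0.5 * texture + 0.45, 0, 1))
        out = reduce_haze(hazy, 0.05)
        assert out.pixels.var() >= hazy.pixels.var()

    def test_amount_out_of_range(self, textured_gray):
        with pytest.raises(ParameterError):
            reduce_haze(textured_gray, 1.5)


class TestStretchWindow:
    def test_identity_when_already_spanning(self):
        pix = np.linspace(0, 1, 400).reshape(20, 20)
        out = stretch_window(_img(pix), clip=0.0)
        np.testing.assert_allclose(out.pixels, pix, atol=1e-12)

    def test_clip_saturation_counts(self, rng):
        pix = rng.uniform(0, 1, size=(100, 100))
        out = stretch_window(_img(pix), clip=0.001)
        n = pix.size
        assert np.sum(out.pixels == 1.0) <= 0.001 * n + 1
        assert np.sum(out.pixels >= 1.0 - 1e-9) >= 0.001 * n

    def test_affine_invariance(self, rng):
        pix = rng.uniform(0.2, 0.8, size=(50, 50))
        a, b = 0.5, 0.1
        out1 = stretch_window(_img(pix), clip=0.01)
        out2 = stretch_window(_img(a * pix + b), clip=0.01)
        np.testing.assert_allclose(out1.pixels, out2.pixels, atol=1e-12)

    def test_idempotent_without_clipping(self, rng):
        pix = rng.uniform(0, 1, size=(64, 64))
        once = stretch_window(_img(pix), clip=0.0)
        twice = stretch_window(once, clip=0.0)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-6)

    def test_nearly_idempotent_with_clipping(self, rng):
        # interpolated quantiles of the saturated output shift slightly, so
        # a clip > 0 rerun is only idempotent to ~1e-4 on 64^2 images
        pix = rng.uniform(0, 1, size=(64, 64))
        once = stretch_window(_img(pix), clip=0.01)
        twice = stretch_window(once, clip=0.01)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-3)

    def test_degenerate_image_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = stretch_window(_img(np.full((20, 20), 0.3)), clip=0.01)
        assert np.all(out.pixels == 0.0)


class TestEstimateSOD:
    def test_exact_line_through_two_points(self):
        assert estimate_sod([(1000, 900), (1100, 990)], 1050) == pytest.approx(945.0)

    def test_zero_residual_on_exact_line(self):
        pairs = [(s, 0.9 * s + 10) for s in (900, 1000, 1100, 1200)]
        for q in (950, 1050, 1300):
            assert estimate_sod(pairs, q) == pytest.approx(0.9 * q + 10, abs=1e-9)

    def test_ols_recovers_slope_from_noise(self, rng):
        sids = rng.uniform(900, 1300, size=80)
        sods = 0.85 * sids + 25 + rng.normal(0, 5, size=80)
        est_at_0 = estimate_sod(list(zip(sids, sods)), 0.0)
        est_at_1 = estimate_sod(list(zip(sids, sods)), 1.0)
        slope = est_at_1 - est_at_0
        assert slope == pytest.approx(0.85, abs=0.02)

    def test_equal_sids_rejected(self):
        with pytest.raises(DataError):
            estimate_sod([(1000, 900), (1000, 950)], 1000)


class TestNormalizeMagnification:
    def test_unit_magnification_identity(self, textured_gray):
        cal = GeometryCalibration(sid_mm=1000, sod_mm=1000)
        out = normalize_magnification(textured_gray, cal, textured_gray.spacing_mm)
        np.testing.assert_array_equal(out.pixels, textured_gray.pixels)

    def test_magnification_two_halves_dimensions(self, textured_gray):
        cal = GeometryCalibration(sid_mm=2000, sod_mm=1000)
        out = normalize_magnification(textured_gray, cal, textured_gray.spacing_mm)
        assert out.shape == (64, 64)

    def test_sod_greater_than_sid_rejected(self):
        with pytest.raises(CalibrationError):
            GeometryCalibration(sid_mm=1000, sod_mm=1100)

    def test_round_trip_correlation(self):
        yy, xx = np.mgrid[0:128, 0:128] / 128.0
        smooth = 0.5 + 0.3 * np.sin(4 * xx) * np.cos(3 * yy)
        img = GrayImage(np.clip(smooth, 0, 1))
        down = normalize_magnification(img, GeometryCalibration(2000, 1000), 1.0)
        up = normalize_magnification(
            GrayImage(down.pixels, spacing_mm=1.0), GeometryCalibration(1000, 1000), 0.5
        )
        r = np.corrcoef(up.pixels.ravel(), img.pixels.ravel())[0, 1]
        assert r > 0.95


class TestROIFromCorners:
    SQUARE = [(0, 0), (10, 0), (10, 10), (0, 10)]

    def test_square_case_exact(self):
        roi = roi_from_corners(self.SQUARE)
        expected = {(5 / 3, 5 / 3), (25 / 3, 5 / 3), (25 / 3, 25 / 3), (5 / 3, 25 / 3)}
        got = {tuple(np.round(v, 9)) for v in roi.vertices}
        want = {tuple(np.round(v, 9)) for v in expected}
        assert got == want
        assert roi.area == pytest.approx(400 / 9)

    def test_parallelogram_centroid_preserved(self):
        corners = [(0, 0), (8, 2), (11, 9), (3, 7)]
        roi = roi_from_corners(corners)
        outer_centroid = np.mean(corners, axis=0)
        np.testing.assert_allclose(roi.centroid, outer_centroid, atol=1e-9)

    def test_similarity_equivariance(self):
        theta = 0.7
        scale = 2.5
        rot = scale * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        corners = np.array([(0, 0), (10, 1), (11, 12), (-1, 9)], dtype=float)
        roi_a = np.asarray(roi_from_corners(corners).vertices)
        roi_b = np.asarray(roi_from_corners(corners @ rot.T).vertices)
        transformed = roi_a @ rot.T
        for v in transformed:
            assert np.min(np.linalg.norm(roi_b - v, axis=1)) < 1e-9

    def test_rasterized_area_matches(self):
        scale = 20
        corners = [(x * scale, y * scale) for x, y in self.SQUARE]
        roi = roi_from_corners(corners)
        mask = roi.rasterize((10 * scale + 1, 10 * scale + 1))
        expected = 400 / 9 * scale**2
        assert mask.sum() == pytest.approx(expected, rel=0.02)

    def test_collinear_corners_rejected(self):
        with pytest.raises(DegeneratePolygonError):
            roi_from_corners([(0, 0), (1, 1), (2, 2), (3, 3)])
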
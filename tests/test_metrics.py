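import math

import numpy as np
import pytest

from mvmar.core import ImageVolume, StructureMask
from mvmar.metrics import (
    MetricParams,
    REDCurve,
    artifact_index,
    default_red_curve,
    hu_to_red,
    psnr,
    roi_red_stats,
    ssim,
    ssim_map,
)


def brute_force_psnr(a, b, max_value=4000.0):
    rmse = math.sqrt(sum((x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())) / a.size)
    return 10.0 * math.log10(max_value**2 / rmse**2)


def _gauss_kernel(window=11, sigma=1.5):
    half = window // 2
    g = np.exp(-np.arange(-half, half + 1) ** 2 / (2 * sigma**2))
    g /= g.sum()
    return np.outer(g, g)


def brute_force_ssim_map(a, b, params=MetricParams()):
    """Sliding-window reference: explicit weighted moments per window."""
    kern = _gauss_kernel(params.window, params.sigma)
    half = params.window // 2
    h, w = a.shape
    out = np.zeros((h - 2 * half, w - 2 * half))
    c1, c2 = params.c1, params.c2
    for i in range(half, h - half):
        for j in range(half, w - half):
            wa = a[i - half : i + half + 1, j - half : j + half + 1]
            wb = b[i - half : i + half + 1, j - half : j + half + 1]
            mu1 = (kern * wa).sum()
            mu2 = (kern * wb).sum()
            s11 = (kern * wa * wa).sum() - mu1**2
            s22 = (kern * wb * wb).sum() - mu2**2
            s12 = (kern * wa * wb).sum() - mu1 * mu2
            out[i - half, j - half] = ((2 * mu1 * mu2 + c1) * (2 * s12 + c2)) / (
                (mu1**2 + mu2**2 + c1) * (s11 + s22 + c2)
            )
    return out


class TestPsnr:
    def test_identical_images_give_infinity_sentinel(self, small_ct):
        assert psnr(small_ct, small_ct) == math.inf

    def test_uniform_offset_closed_form(self):
        a = np.zeros((16, 16))
        b = a + 400.0  # MAX/10 -> PSNR = 10*log10(100) = 20 dB
        assert psnr(a, b) == pytest.approx(20.0, abs=1e-12)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(5):
            a = rng.uniform(-1000, 3000, (32, 32))
            b = a + rng.normal(0, 50, (32, 32))
            assert psnr(a, b) == pytest.approx(brute_force_psnr(a, b), abs=1e-9)

    def test_band_membership_decided_by_reference(self):
        a = np.array([[0.0, 1000.0]])
        b = np.array([[100.0, 1000.0]])
        # band (-200, 400) selects only the first pixel (by reference HU)
        val = psnr(a, b, band=(-200.0, 400.0))
        assert val == pytest.approx(10 * math.log10(4000**2 / 100.0**2))

    def test_empty_band_errors(self):
        a = np.zeros((4, 4))
        with pytest.raises(ValueError, match="band"):
            psnr(a, a, band=(2000.0, 3000.0))

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shapes"):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))


class TestSsim:
    def test_identical_images_give_one(self, rng):
        a = rng.uniform(-1000, 3000, (32, 32))
        assert ssim(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_identical_constants_give_one(self):
        a = np.full((16, 16), 500.0)
        assert ssim(a, a.copy()) == pytest.approx(1.0)

    def test_matches_naive_sliding_window(self, rng):
        a = rng.uniform(-1000, 3000, (24, 24))
        b = a + rng.normal(0, 100, (24, 24))
        np.testing.assert_allclose(ssim_map(a, b), brute_force_ssim_map(a, b), atol=1e-6)

    def test_window_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="window"):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))

    def test_score_within_unit_interval(self, rng):
        a = rng.uniform(-1000, 3000, (20, 20))
        b = rng.uniform(-1000, 3000, (20, 20))
        assert -1.0 <= ssim(a, b) <= 1.0


class TestRedCurve:
    def test_calibration_knots_read_back_exactly(self):
        curve = default_red_curve("ct")
        vol = ImageVolume(np.array([[0.0, 3500.0, 4000.0, 3000.0]]), (1.0, 1.0))
        red = hu_to_red(vol, curve)
        assert red[0, 0] == 1.0  # water
        assert red[0, 1] == 3.73  # titanium alloy
        assert red[0, 2] == 6.83  # stainless steel
        assert red[0, 3] == 2.43  # aluminium alloy

    def test_monotone_for_every_default_curve(self):
        hu = np.linspace(-1500, 5000, 2001)
        for modality in ("ct", "mv"):
            red = default_red_curve(modality)(hu)
            assert np.all(np.diff(red) >= 0)

    def test_floor_and_flat_extrapolation(self):
        curve = REDCurve(hu=[0.0, 100.0], red=[1.0, 1.1])
        assert curve(np.array([-500.0]))[0] == 0.0
        assert curve(np.array([500.0]))[0] == 1.1

    def test_rejects_non_monotone_knots(self):
        with pytest.raises(ValueError, match="increasing"):
            REDCurve(hu=[0.0, 0.0], red=[1.0, 1.1])
        with pytest.raises(ValueError, match="non-decreasing"):
            REDCurve(hu=[0.0, 100.0], red=[1.1, 1.0])

    def test_mv_and_ct_curves_differ_in_soft_tissue(self):
        # the CT-ED relation differs between modalities: the same physical
        # tissue maps to different HU, so the curves cannot coincide
        ct, mv = default_red_curve("ct"), default_red_curve("mv")
        assert ct(np.array([100.0]))[0] != mv(np.array([100.0]))[0]


class TestRoiRedStats:
    def test_constant_region(self):
        red = np.full((8, 8), 1.0)
        mask = StructureMask("oral_cavity", np.ones((8, 8), dtype=bool))
        stats = roi_red_stats(red, mask)
        assert stats["mean"] == 1.0 and stats["std"] == 0.0

    def test_two_pixel_mean(self):
        red = np.array([[1.0, 1.2]])
        mask = StructureMask("roi", np.array([[True, True]]))
        assert roi_red_stats(red, mask)["mean"] == pytest.approx(1.1)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            roi_red_stats(np.ones((4, 4)), StructureMask("roi", np.zeros((4, 4), dtype=bool)))


class TestArtifactIndex:
    @staticmethod
    def _uniform_setup():
        truth = ImageVolume(np.full((64, 64), 40.0), (1.0, 1.0))
        soft = StructureMask("soft_tissue", np.ones((64, 64), dtype=bool))
        return truth, soft

    def test_zero_for_perfect_reconstruction(self):
        truth, soft = self._uniform_setup()
        assert artifact_index(truth, soft, truth=truth) == 0.0

    def test_positive_and_monotone_in_streak_amplitude(self):
        truth, soft = self._uniform_setup()
        indexes = []
        for amp in (250.0, 500.0):
            vals = truth.values.copy()
            vals[:, 18:22] += amp  # a bright streak band crossing the mask
            vals[:, 38:42] -= amp  # and a matching dark one
            idx = artifact_index(truth.with_values(vals), soft, truth=truth)
            assert idx > 0
            indexes.append(idx)
        assert indexes[1] > indexes[0]

    def test_restricts_to_neighbourhood_of_metal(self):
        truth, soft = self._uniform_setup()
        metal = np.zeros((64, 64), dtype=bool)
        metal[32, 32] = True
        vals = truth.values.copy()
        vals[0, 0] += 5000.0  # corruption far from metal (> 30 mm away)
        idx = artifact_index(truth.with_values(vals), soft, StructureMask("metal", metal), truth=truth)
        assert idx == 0.0

    def test_empty_soft_mask_errors(self):
        truth, _ = self._uniform_setup()
        with pytest.raises(ValueError, match="empty"):
            artifact_index(truth, StructureMask("soft_tissue", np.zeros((64, 64), dtype=bool)))
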
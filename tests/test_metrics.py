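"""Masked metrics, FWHM width fitting and peak-interval measurements."""

import numpy as np
import pytest

from mitorestore.metrics import (
    GAUSSIAN_FWHM_FACTOR,
    LineProfile,
    ProfileFitError,
    evaluate_dataset,
    fwhm_width,
    masked_nrmse,
    masked_psnr,
    masked_ssim,
    peak_to_peak_intervals,
    sample_line_profile,
)


class TestMaskedNRMSE:
    def test_perfect_prediction_zero(self, rng):
        y = rng.random((32, 32))
        mask = rng.random((32, 32)) < 0.4
        assert masked_nrmse(y, y.copy()) == 0.0
        assert masked_nrmse(y, y.copy(), mask) == 0.0

    def test_checkerboard_worked_value(self):
        y = np.indices((64, 64)).sum(axis=0) % 2
        assert masked_nrmse(y.astype(float), np.zeros((64, 64))) == pytest.approx(
            np.sqrt(0.5)
        )

    def test_masking_semantics(self, rng):
        y = rng.random((32, 32))
        y_hat = y.copy()
        y_hat[:, 16:] += 0.5  # break the right half only
        left = np.zeros((32, 32), dtype=bool)
        left[:, :16] = True
        assert masked_nrmse(y, y_hat, left) == 0.0
        assert masked_nrmse(y, y_hat) > 0.0

    def test_mean_normalization_variant(self, rng):
        y = rng.random((32, 32)) + 1.0
        y_hat = y + 0.1
        r = masked_nrmse(y, y_hat, normalization="range")
        m = masked_nrmse(y, y_hat, normalization="mean")
        assert r > 0 and m > 0 and r != m

    def test_errors(self):
        y = np.ones((8, 8))
        with pytest.raises(ValueError):
            masked_nrmse(y, y, np.zeros((8, 8), dtype=bool))  # empty mask
        with pytest.raises(ValueError):
            masked_nrmse(y, y + 1)  # zero dynamic range


class TestMaskedPSNR:
    def test_worked_value(self):
        y = np.zeros((100, 100))
        y[::2] = 1.0  # range 1
        y_hat = y + 0.5  # MSE = 0.25
        assert masked_psnr(y, y_hat) == pytest.approx(10 * np.log10(4), abs=1e-9)
        assert masked_psnr(y, y_hat) == pytest.approx(6.02, abs=0.01)

    def test_perfect_match_sentinel(self, rng):
        y = rng.random((16, 16))
        assert masked_psnr(y, y.copy()) == float("inf")

    def test_masked_ge_full_when_error_outside_mask(self, rng):
        y = rng.random((32, 32))
        y_hat = y.copy()
        y_hat[:, 16:] += 0.3
        mask = np.zeros((32, 32), dtype=bool)
        mask[:, :16] = True
        assert masked_psnr(y, y_hat, mask) > masked_psnr(y, y_hat)


class TestMaskedSSIM:
    def test_identity_and_full_mask_consistency(self, rng):
        y = rng.random((64, 64))
        y_hat = np.clip(y + rng.normal(0, 0.1, y.shape), 0, 1)
        assert masked_ssim(y, y.copy()) == pytest.approx(1.0)
        full = masked_ssim(y, y_hat, np.ones((64, 64), dtype=bool))
        assert full == pytest.approx(masked_ssim(y, y_hat), abs=1e-12)

    def test_uncorrelated_noise_near_zero(self):
        r = np.random.default_rng(0)
        y, y_hat = r.random((128, 128)), r.random((128, 128))
        assert abs(masked_ssim(y, y_hat)) < 0.15


class TestEvaluateDataset:
    def test_perfect_pair_summary(self, rng):
        y = rng.random((64, 64))
        mito = rng.random((64, 64)) < 0.3
        cristae = mito & (rng.random((64, 64)) < 0.5)
        with pytest.warns(UserWarning, match="sentinel"):
            report = evaluate_dataset([(y, y.copy())], [(mito, cristae)])
        assert len(report.per_image) == 1
        for scope in ("full", "mito", "cristae"):
            assert report.per_image[f"nrmse_{scope}"][0] == 0.0
            assert np.isinf(report.per_image[f"psnr_{scope}"][0])
            assert report.per_image[f"ssim_{scope}"][0] == pytest.approx(1.0)
        assert np.isnan(report.mean["psnr_full"])  # sentinel excluded

    def test_row_per_evaluable_image(self, rng):
        pairs, masks = [], []
        for _ in range(3):
            y = rng.random((64, 64))
            pairs.append((y, np.clip(y + rng.normal(0, 0.1, y.shape), 0, 1)))
            m = rng.random((64, 64)) < 0.3
            masks.append((m, m & (rng.random((64, 64)) < 0.5)))
        report = evaluate_dataset(pairs, masks)
        assert len(report.per_image) == 3
        assert set(report.summary().columns) == {"mean", "sd"}

    def test_bad_image_skipped_with_warning(self, rng):
        y = rng.random((64, 64))
        good = ((y > 0.5), (y > 0.8))
        empty = (np.zeros((64, 64), dtype=bool), np.zeros((64, 64), dtype=bool))
        with pytest.warns(UserWarning, match="skipped"):
            report = evaluate_dataset([(y, y + 0.1), (y, y + 0.1)], [good, empty])
        assert len(report.per_image) == 1


class TestFWHM:
    @staticmethod
    def _gaussian_profile(sigma=2.0, noise=0.0, seed=0, pixel_size=25.0):
        x = np.arange(0.0, 40.0, 0.25)
        v = 100.0 * np.exp(-((x - 20.0) ** 2) / (2 * sigma**2)) + 10.0
        if noise:
            v = v + np.random.default_rng(seed).normal(0, noise * 100.0, v.shape)
        return LineProfile(x, v, pixel_size=pixel_size)

    def test_noiseless_closed_form(self):
        fit = fwhm_width(self._gaussian_profile(sigma=2.0))
        assert fit.fwhm_nm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2 * 25, rel=1e-6)
        assert fit.fwhm_nm == pytest.approx(117.74, abs=0.01)

    @pytest.mark.parametrize("sigma", [1.0, 3.0, 6.0])
    def test_unbiased_across_widths(self, sigma):
        fit = fwhm_width(self._gaussian_profile(sigma=sigma))
        assert fit.sigma == pytest.approx(sigma, rel=1e-3)

    def test_robust_to_noise(self):
        target = GAUSSIAN_FWHM_FACTOR * 2 * 25
        fits = [
            fwhm_width(self._gaussian_profile(sigma=2.0, noise=0.05, seed=s)).fwhm_nm
            for s in range(30)
        ]
        assert np.all(np.abs(np.array(fits) - target) / target < 0.10)

    def test_flat_profile_raises(self):
        flat = LineProfile(np.arange(10.0), np.full(10, 3.0), 25.0)
        with pytest.raises(ProfileFitError):
            fwhm_width(flat)

    def test_result_invariant(self):
        fit = fwhm_width(self._gaussian_profile(sigma=2.5))
        assert fit.fwhm_nm == pytest.approx(GAUSSIAN_FWHM_FACTOR * fit.sigma * 25.0)


class TestPeakIntervals:
    def test_worked_example(self):
        x = np.arange(0.0, 15.0, 0.25)
        v = np.cos(2 * np.pi * x / 5.0)  # peaks at 0, 5, 10
        prof = LineProfile(x, v, pixel_size=25.0)
        iv = peak_to_peak_intervals(prof)
        assert np.allclose(iv, [125.0, 125.0], atol=12.5)

    def test_monotone_profile_empty(self):
        prof = LineProfile(np.arange(10.0), np.arange(10.0) * 2.0, 25.0)
        assert len(peak_to_peak_intervals(prof)) == 0

    def test_flat_profile_empty(self):
        prof = LineProfile(np.arange(10.0), np.full(10, 1.0), 25.0)
        assert len(peak_to_peak_intervals(prof)) == 0


class TestLineProfileSampling:
    def test_profile_matches_image_values(self):
        img = np.tile(np.arange(64.0), (64, 1))  # intensity = column index
        prof = sample_line_profile(img, (32, 10), (32, 50), pixel_size=25.0)
        assert prof.intensities[0] == pytest.approx(10.0)
        assert prof.intensities[-1] == pytest.approx(50.0)
        assert np.all(np.diff(prof.positions) > 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            LineProfile(np.arange(3.0), np.arange(3.0), 25.0)  # too short
        with pytest.raises(ValueError):
            sample_line_profile(np.ones((8, 8)), (2, 2), (2, 2))
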
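"""Normalization, noise-aware saliency chain, ROI sampling, augmentation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitorestore.degradation import DegradationParams
from mitorestore.sampling import (
    NormalizationParams,
    SamplingConfig,
    adaptive_threshold_mask,
    anscombe_transform,
    augment_pairs,
    build_training_set,
    estimate_noise_stats,
    invert_augmentation,
    mito_mask_from_raw,
    patch_budget,
    percentile_normalize,
    select_roi_centers,
    zscore_map,
)


class TestPercentileNormalize:
    def test_ramp_percentiles_pinned(self):
        img = np.linspace(0.0, 1000.0, 10**6).reshape(1000, 1000)
        out = percentile_normalize(img)
        assert np.percentile(out, 2) == pytest.approx(0.0, abs=1e-12)
        assert np.percentile(out, 99.8) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_point(self, rng):
        img = rng.random((200, 200))
        once = percentile_normalize(img)
        twice = percentile_normalize(once)
        assert np.allclose(once, twice, atol=1e-12)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b):
        img = np.random.default_rng(0).random((64, 64)) * 10
        assert np.allclose(
            percentile_normalize(a * img + b), percentile_normalize(img), atol=1e-9
        )

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            percentile_normalize(np.full((32, 32), 3.0))

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValueError):
            NormalizationParams(p_low=50, p_high=10)


class TestAnscombe:
    def test_known_values(self):
        assert anscombe_transform(np.zeros((2, 2)))[0, 0] == pytest.approx(
            2 * np.sqrt(3 / 8)
        )
        assert anscombe_transform(np.full((2, 2), 13 / 8))[0, 0] == pytest.approx(
            2 * np.sqrt(2)
        )

    def test_stabilizes_poisson_variance(self):
        rng = np.random.default_rng(5)
        for lam in (10.0, 100.0):
            draws = rng.poisson(lam, size=10**5).astype(float)
            assert anscombe_transform(draws.reshape(-1, 1)).var() == pytest.approx(
                1.0, rel=0.05
            )

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            anscombe_transform(np.full((2, 2), -1.0))


class TestNoiseStats:
    def test_constant_image(self):
        s = estimate_noise_stats(np.full((16, 16), 7.0))
        assert s.mu_hat == 7.0
        assert s.sigma_hat == 0.0

    @pytest.mark.parametrize("sd", [1.0, 4.0])
    def test_white_noise_recovery(self, sd):
        field = np.random.default_rng(int(sd)).normal(0.0, sd, (512, 512))
        s = estimate_noise_stats(field)
        assert s.sigma_hat == pytest.approx(sd, rel=0.05)

    def test_edges_barely_affect_sigma(self):
        rng = np.random.default_rng(8)
        img = np.zeros((512, 512))
        img[:, 256:] = 100.0  # one strong edge
        img += rng.normal(0.0, 2.0, img.shape)
        s = estimate_noise_stats(img)
        assert s.sigma_hat == pytest.approx(2.0, rel=0.05)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_stats(np.ones((1, 5)))


class TestZScore:
    def test_median_pixel_maps_to_zero(self):
        rng = np.random.default_rng(1)
        img = rng.normal(10.0, 2.0, (128, 128))
        stats = estimate_noise_stats(img)
        z = zscore_map(img, stats)
        assert np.interp(stats.mu_hat, np.sort(img.ravel()), np.sort(z.ravel())) == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_gaussian_tail_fraction(self):
        img = np.random.default_rng(2).normal(0.0, 5.0, (1024, 1024))
        z = zscore_map(img, estimate_noise_stats(img))
        assert np.mean(np.abs(z) > 3) == pytest.approx(0.0027, rel=0.25)

    def test_bright_object_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        img = rng.normal(0.0, 1.0, (256, 256))
        img[100:120, 100:120] += 50.0
        z = zscore_map(img, estimate_noise_stats(img))
        assert np.median(z[100:120, 100:120]) > 30

    def test_degenerate_sigma_rejected(self):
        from mitorestore.sampling import NoiseStats

        with pytest.raises(ValueError):
            zscore_map(np.ones((4, 4)), NoiseStats(mu_hat=1.0, sigma_hat=0.0))


class TestAdaptiveThreshold:
    def test_bright_object_passes_first_threshold(self):
        z = np.zeros((100, 100))
        z[:20, :] = 50.0  # 20% of pixels well above c0 = 30
        mask = adaptive_threshold_mask(z)
        assert mask.mean() == pytest.approx(0.20, abs=0.02)

    def test_noise_only_image_terminates(self):
        z = np.random.default_rng(4).normal(0.0, 1.0, (256, 256))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            mask = adaptive_threshold_mask(z)
        # threshold relaxes until the mask reaches 10% or the positive floor
        assert mask.mean() >= 0.10 or any("floor" in str(w.message) for w in rec)

    def test_shift_invariance_through_full_chain(self, degraded_phantom):
        img = np.maximum(degraded_phantom, 0.0)
        m1 = mito_mask_from_raw(img)
        m2 = mito_mask_from_raw(img + 50.0)
        # the additive offset shifts mu_hat; Anscombe is nonlinear, so demand
        # near-identity rather than bit-identity
        assert (m1 ^ m2).mean() < 0.02

    def test_nonfinite_rejected(self):
        z = np.zeros((8, 8))
        z[0, 0] = np.nan
        with pytest.raises(ValueError):
            adaptive_threshold_mask(z)


class TestRoiSelection:
    def test_patch_budget_formula(self):
        assert patch_budget((256, 512)) == 8
        assert patch_budget((192, 256)) == 2
        assert patch_budget((127, 128)) == 0

    def test_single_blob_gives_one_center_with_warning(self):
        mask = np.zeros((256, 256), dtype=bool)
        mask[120:130, 120:130] = True
        with pytest.warns(UserWarning, match="admit only"):
            centers = select_roi_centers(mask, (256, 256), SamplingConfig(seed=0))
        assert len(centers) == 1

    def test_constraints_hold_over_seeds(self, phantom_sample):
        mask = phantom_sample.mito_mask
        cfg = SamplingConfig()
        n_target = patch_budget(mask.shape)
        for seed in range(25):
            rng = np.random.default_rng(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                centers = select_roi_centers(mask, mask.shape, cfg, rng)
            assert 1 <= len(centers) <= n_target
            for r, c in centers:
                assert mask[r, c]
                assert 64 <= r <= mask.shape[0] - 64
                assert 64 <= c <= mask.shape[1] - 64
            for i, a in enumerate(centers):
                for b in centers[i + 1 :]:
                    assert np.hypot(a[0] - b[0], a[1] - b[1]) >= 60

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no eligible"):
            select_roi_centers(np.zeros((256, 256), dtype=bool), (256, 256))


class TestAugmentation:
    def test_rotations_quadruple_the_set(self, rng):
        pairs = [(rng.random((32, 32)), rng.random((32, 32))) for _ in range(24)]
        out = augment_pairs(pairs, seed=0)
        assert len(out) == 96

    def test_round_trip_for_pure_rotations(self, rng):
        lr, hr = rng.random((32, 32)), rng.random((32, 32))
        out, records = augment_pairs([(lr, hr)], seed=0, return_records=True)
        for (lr_a, hr_a), rec in zip(out, records):
            if rec.shrunk:
                continue  # shrink is lossy by design
            assert np.array_equal(invert_augmentation(lr_a, rec), lr)
            assert np.array_equal(invert_augmentation(hr_a, rec), hr)

    def test_co_registration_preserved(self, rng):
        img = rng.random((48, 48))
        out, records = augment_pairs([(img, img.copy())], seed=3, return_records=True)
        assert any(r.shrunk for r in records)  # 25% of 4 rounds to 1
        for lr_a, hr_a in out:
            assert np.array_equal(lr_a, hr_a)

    def test_symmetric_content_not_deduplicated(self):
        yy, xx = np.mgrid[:33, :33]
        disk = ((yy - 16) ** 2 + (xx - 16) ** 2 <= 100).astype(float)
        out = augment_pairs([(disk, disk.copy())], seed=1)
        assert len(out) == 4  # duplicates kept

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_pairs([(rng.random((8, 8)), rng.random((9, 8)))])


@pytest.fixture(scope="module")
def patch_sets():
    from mitorestore.phantom import PhantomConfig, generate_dataset

    samples = generate_dataset(PhantomConfig(image_size=(192, 256), seed=21), 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_training_set(
            [s.hr_image for s in samples],
            params=DegradationParams(seed=2),
            config=SamplingConfig(seed=2),
        )


class TestBuildTrainingSet:
    def test_split_is_80_20_and_disjoint(self, patch_sets):
        train, val = patch_sets
        n = len(train) + len(val)
        assert len(val) == int(round(0.2 * n))
        train_ids = {(p.origin, p.lr_patch.tobytes()) for p in train}
        val_ids = {(p.origin, p.lr_patch.tobytes()) for p in val}
        assert not train_ids & val_ids

    def test_patch_invariants(self, patch_sets):
        train, val = patch_sets
        for p in train + val:
            assert p.lr_patch.shape == p.hr_patch.shape == p.gamma_map.shape == (128, 128)
            assert set(np.unique(p.gamma_map)) <= {1.0, 4.0}

    def test_patch_count_follows_budget(self, patch_sets):
        # 4 images x 4 augmentations x N_I(192x256) = 2 patches, minus any
        # frames where constraints admit fewer
        train, val = patch_sets
        assert 16 <= len(train) + len(val) <= 32

    def test_sampler_prefers_mitochondria(self, patch_sets):
        """Patches must be enriched in mitochondria vs. the whole frame."""
        train, val = patch_sets
        patch_frac = np.mean([(p.gamma_map == 1.0).mean() for p in train + val])
        # phantom frames carry ~10-30% mitochondria pixels; sampled patches
        # are centered on them so they must be enriched
        assert patch_frac > 0.15

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_training_set([])
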
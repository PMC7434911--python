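"""Noise model, air-ROI calibration and k-space undersampling."""

import numpy as np
import pytest

from vwdenoise.corruption import (NoiseSpec, add_noise, estimate_air_noise,
                                  poisson_disk_mask, zero_fill_reconstruct)
from vwdenoise.phantom import GrayImage, generate_phantom
from vwdenoise.quality import snr_region

from conftest import small_phantom_spec


def _flat(value, shape=(256, 256)):
    return GrayImage(pixels=np.full(shape, float(value)))


class TestAddNoise:
    def test_zero_fraction_is_identity(self):
        img = _flat(100)
        out = add_noise(img, NoiseSpec(sigma_frac_range=(0.0, 0.0)), seed=0)
        assert np.array_equal(out.pixels, img.pixels)

    def test_sigma_is_fraction_of_arithmetic_mean(self):
        """Constant 100 with sigma_frac 0.3 -> empirical std 30 +- 1 on 65536 draws."""
        img = _flat(100)
        out = add_noise(img, NoiseSpec(sigma_frac_range=(0.3, 0.3)), seed=1)
        assert np.std(out.pixels - img.pixels) == pytest.approx(30.0, abs=1.0)

    def test_default_range_is_25_to_35_percent(self):
        assert NoiseSpec().sigma_frac_range == (0.25, 0.35)

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_preserved_within_sampling_error(self, seed):
        img = _flat(50, (128, 128))
        out, sigma = add_noise(img, NoiseSpec(sigma_frac_range=(0.25, 0.35)),
                               seed=seed, return_sigma=True)
        tol = 3 * sigma / np.sqrt(img.pixels.size)
        assert abs(out.pixels.mean() - img.pixels.mean()) < tol

    def test_rician_with_nonzero_mu_rejected(self):
        with pytest.raises(ValueError, match="Rician"):
            NoiseSpec(family="rician", mu=1.0)

    def test_rician_acts_on_magnitude(self):
        img = _flat(0.0)
        out = add_noise(img, NoiseSpec(family="rician", sigma_frac_range=(0.3, 0.3)))
        # zero-signal Rician noise is Rayleigh: strictly non-negative
        img2 = GrayImage(pixels=np.full((256, 256), 100.0))
        out2 = add_noise(img2, NoiseSpec(family="rician", sigma_frac_range=(0.3, 0.3)), seed=2)
        assert (out2.pixels >= 0).all()

    def test_inhomogeneous_noise_varies_spatially(self):
        img = _flat(100)
        spec = NoiseSpec(sigma_frac_range=(0.3, 0.3),
                         inhomogeneity={"strength": 0.8, "scale": 16})
        out = add_noise(img, spec, seed=3)
        resid = out.pixels - img.pixels
        tiles = resid.reshape(8, 32, 8, 32).std(axis=(1, 3))
        assert tiles.max() > 1.5 * tiles.min()


class TestAirNoise:
    def test_recovers_known_sigma_and_normal_verdict(self):
        """Monte-Carlo calibration: sigma within 2% relative bias at n = 1e4."""
        sigmas, verdicts = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            roi = rng.normal(0, 5.0, 10_000)
            sigma, res = estimate_air_noise(roi, None)
            sigmas.append(sigma)
            verdicts.append(res.normal)
        assert abs(np.mean(sigmas) - 5.0) / 5.0 < 0.02
        assert np.mean(verdicts) >= 0.99

    def test_uniform_noise_rejected_as_non_normal(self):
        verdicts = [estimate_air_noise(np.random.default_rng(s).uniform(0, 1, 10_000),
                                       None)[1].normal for s in range(100)]
        assert np.mean(verdicts) <= 0.01

    def test_acceptance_threshold_is_p_above_001(self):
        _, res = estimate_air_noise(np.random.default_rng(0).normal(0, 1, 1000), None)
        assert res.alpha == 0.01
        assert res.normal == (res.p_value > 0.01)

    def test_small_or_constant_roi_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            estimate_air_noise(np.zeros(10), None)
        with pytest.raises(ValueError, match="constant"):
            estimate_air_noise(np.zeros(100), None)

    def test_air_roi_on_image_with_box(self):
        img, rois = generate_phantom(small_phantom_spec(seed=1))
        noisy = add_noise(img, NoiseSpec(sigma_frac_range=(0.3, 0.3)), seed=4)
        sigma_true = 0.3 * img.pixels.mean()
        sigma, res = estimate_air_noise(noisy, rois["air"])
        assert sigma == pytest.approx(sigma_true, rel=0.05)


class TestPoissonDiskMask:
    def test_acceleration_one_is_full(self):
        assert poisson_disk_mask((64, 64), 1, seed=0).mask.all()

    def test_invalid_acceleration(self):
        with pytest.raises(ValueError):
            poisson_disk_mask((64, 64), 0.5)

    @pytest.mark.parametrize("accel", [2, 4, 8])
    def test_sampled_fraction_matches_target(self, accel):
        mask = poisson_disk_mask((256, 256), accel, seed=3)
        assert mask.fraction == pytest.approx(1 / accel, rel=0.1)
        assert mask.mask[128, 128]  # DC sampled

    def test_deterministic(self):
        a = poisson_disk_mask((128, 128), 4, seed=7)
        b = poisson_disk_mask((128, 128), 4, seed=7)
        assert np.array_equal(a.mask, b.mask)

    def test_centre_denser_than_edge(self):
        mask = poisson_disk_mask((256, 256), 4, seed=0).mask
        centre = mask[96:160, 96:160].mean()
        corner = mask[:64, :64].mean()
        assert centre > 1.5 * corner


class TestZeroFill:
    def test_full_mask_is_identity(self, phantom_and_rois):
        img, _ = phantom_and_rois
        mask = poisson_disk_mask(img.shape, 1)
        out = zero_fill_reconstruct(img, mask)
        assert np.max(np.abs(out.pixels - img.pixels)) < 1e-9 * img.pixels.max()

    def test_undersampling_loses_information(self, phantom_and_rois):
        img, _ = phantom_and_rois
        mask = poisson_disk_mask(img.shape, 4, seed=1)
        out = zero_fill_reconstruct(img, mask)
        assert np.mean((out.pixels - img.pixels) ** 2) > 0

    def test_artefact_grows_with_acceleration(self):
        """Parenchyma ROI noise is larger at acceleration 4 than 2 (seeded)."""
        noises = {}
        for accel in (2, 4):
            vals = []
            for seed in range(3):
                img, rois = generate_phantom(small_phantom_spec(seed=seed))
                mask = poisson_disk_mask(img.shape, accel, seed=seed)
                out = zero_fill_reconstruct(img, mask)
                vals.append(snr_region(out, rois["parenchyma"])[1])
            noises[accel] = np.mean(vals)
        assert noises[4] > noises[2]

    def test_linear_and_idempotent_for_fixed_mask(self, phantom_and_rois):
        img, _ = phantom_and_rois
        mask = poisson_disk_mask(img.shape, 2, seed=5)
        once = zero_fill_reconstruct(img, mask, magnitude=False)
        twice = zero_fill_reconstruct(once, mask, magnitude=False)
        assert np.allclose(twice.pixels, once.pixels, atol=1e-9 * img.pixels.max())
        # linearity on the signed reconstruction
        a, _ = generate_phantom(small_phantom_spec(seed=11))
        fa = zero_fill_reconstruct(a, mask, magnitude=False).pixels
        fi = zero_fill_reconstruct(img, mask, magnitude=False).pixels
        both = GrayImage(pixels=a.pixels + img.pixels)
        fboth = zero_fill_reconstruct(both, mask, magnitude=False).pixels
        assert np.allclose(fboth, fa + fi, atol=1e-8 * both.pixels.max())

    def test_shape_mismatch_rejected(self, phantom_and_rois):
        img, _ = phantom_and_rois
        with pytest.raises(ValueError, match="shape"):
            zero_fill_reconstruct(img, poisson_disk_mask((128, 128), 2))
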
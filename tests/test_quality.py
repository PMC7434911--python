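"""ROI noise/SNR, noise maps, BRISQUE statistics and the statistical tests."""

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from vwdenoise.corruption import NoiseSpec, add_noise
from vwdenoise.phantom import GrayImage, generate_phantom
from vwdenoise.quality import (BrisqueScorer, UndefinedSNRError, brisque_features,
                               brisque_score, dagostino_normality, evaluate_image,
                               ks_normality, noise_map, paired_t_test, snr_region,
                               snr_vessel_wall)

from conftest import small_phantom_spec


class TestSnr:
    def test_vessel_wall_quotient(self):
        arr = np.zeros((64, 64))
        arr[10:20, 10:20] = 200.0           # wall, peak 200
        rng = np.random.default_rng(0)
        arr[30:50, 30:50] = rng.normal(50, 20, (20, 20))  # lumen
        wall = np.zeros((64, 64), dtype=bool); wall[10:20, 10:20] = True
        lumen = np.zeros((64, 64), dtype=bool); lumen[30:50, 30:50] = True
        signal, noise, snr = snr_vessel_wall(arr, wall, lumen)
        assert signal == 200.0
        assert noise == pytest.approx(20.0, abs=2.0)
        assert snr == pytest.approx(signal / noise)

    def test_constant_lumen_is_undefined(self, phantom_and_rois):
        img, rois = phantom_and_rois
        with pytest.raises(UndefinedSNRError):
            snr_vessel_wall(img, rois["vessel_wall"], rois["lumen"])

    def test_lumen_noise_recovers_injected_sigma(self):
        """Phantom + sigma = 10 noise: a ~400-pixel lumen reads std 10 +- 1."""
        img, rois = generate_phantom(
            small_phantom_spec(seed=3, size=(128, 128), vessel_radius_range=(8.0, 9.0)))
        assert rois["lumen"].sum() >= 400
        sigma = 10.0
        frac = sigma / img.pixels.mean()
        noisy = add_noise(img, NoiseSpec(sigma_frac_range=(frac, frac)), seed=1)
        _, noise, _ = snr_vessel_wall(noisy, rois["vessel_wall"], rois["lumen"])
        assert noise == pytest.approx(sigma, abs=1.0)

    def test_region_snr_from_known_moments(self):
        rng = np.random.default_rng(1)
        roi_vals = rng.normal(100, 10, (100, 100))
        signal, noise, snr = snr_region(roi_vals, np.ones((100, 100), dtype=bool))
        assert snr == pytest.approx(10.0, abs=0.2)

    def test_constant_region_is_undefined(self):
        with pytest.raises(UndefinedSNRError):
            snr_region(np.full((10, 10), 50.0), np.ones((10, 10), dtype=bool))

    @pytest.mark.parametrize("seed", range(10))
    def test_added_noise_lowers_snr(self, seed):
        img, rois = generate_phantom(small_phantom_spec(seed=seed))
        noisy = add_noise(img, NoiseSpec(sigma_frac_range=(0.3, 0.3)), seed=seed)
        _, _, snr_clean = snr_region(img, rois["parenchyma"])
        _, _, snr_noisy = snr_region(noisy, rois["parenchyma"])
        assert snr_noisy < snr_clean

    def test_translation_covariance(self):
        """Adding c shifts Eq.7 signal by c and leaves noise unchanged."""
        rng = np.random.default_rng(2)
        vals = rng.normal(50, 5, (64, 64))
        roi = np.ones((64, 64), dtype=bool)
        s0, n0, _ = snr_region(vals, roi)
        s1, n1, _ = snr_region(vals + 17.0, roi)
        assert s1 == pytest.approx(s0 + 17.0)
        assert n1 == pytest.approx(n0)


class TestNoiseMap:
    def test_constant_image_is_all_zero(self):
        assert (noise_map(np.full((50, 50), 7.0)).values == 0).all()

    def test_window_validation(self):
        with pytest.raises(ValueError):
            noise_map(np.zeros((50, 50)), window=4)

    def test_iid_noise_matches_c4_corrected_sigma(self):
        """Tile-mean of sample std approaches c4(25) * sigma; within 5% of sigma."""
        rng = np.random.default_rng(0)
        sigma = 3.0
        arr = rng.normal(0, sigma, (500, 500))  # 10,000 tiles of 5x5
        nm = noise_map(arr)
        n = 25
        c4 = np.sqrt(2 / (n - 1)) * gamma_fn(n / 2) / gamma_fn((n - 1) / 2)
        assert nm.values.mean() == pytest.approx(c4 * sigma, rel=0.01)
        assert abs(nm.values.mean() - sigma) / sigma < 0.05

    def test_locality(self):
        arr = np.zeros((50, 100))
        arr[:, 50:] = np.random.default_rng(1).normal(0, 5, (50, 50))
        nm = noise_map(arr).values
        assert (nm[:, :10] == 0).all() and (nm[:, 10:] > 0).all()

    def test_sliding_variant_is_dense(self):
        arr = np.random.default_rng(0).normal(0, 1, (40, 40))
        assert noise_map(arr, sliding=True).values.shape == (40, 40)


class TestBrisque:
    def test_feature_vector_has_36_finite_entries(self, phantom_and_rois):
        f = brisque_features(phantom_and_rois[0])
        assert f.shape == (36,) and np.all(np.isfinite(f))

    def test_features_deterministic(self, phantom_and_rois):
        a = brisque_features(phantom_and_rois[0])
        b = brisque_features(phantom_and_rois[0])
        assert np.array_equal(a, b)

    def test_ggd_fit_recovers_gaussian_shape(self):
        """The moment-matched GGD fit reads alpha = 2 on raw Gaussian draws."""
        from vwdenoise.quality import _fit_ggd

        alpha, var = _fit_ggd(np.random.default_rng(3).normal(0, 1, 1_000_000))
        assert 1.9 <= alpha <= 2.1
        assert var == pytest.approx(1.0, rel=0.01)

    def test_mscn_of_gaussian_noise_is_mildly_platykurtic(self):
        """MSCN of iid Gaussian noise: the 7x7 local normalisation window
        includes each pixel in its own sigma estimate, compressing tails, so
        the fitted shape sits above 2 (about 3 at this window; it approaches
        2 as the window grows)."""
        arr = np.random.default_rng(3).normal(100, 10, (1000, 1000))
        alpha = brisque_features(arr)[0]
        assert 2.6 <= alpha <= 3.3

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            brisque_features(np.full((64, 64), 5.0))

    def test_scorer_requires_configuration(self):
        with pytest.raises(ValueError, match="scorer"):
            brisque_score(np.zeros(36), None)

    def test_scores_bounded_and_clean_near_corpus_floor(self):
        clean = [generate_phantom(small_phantom_spec(seed=s))[0] for s in range(8)]
        scorer = BrisqueScorer().fit(clean)
        scores_clean = [brisque_score(brisque_features(img), scorer) for img in clean]
        noisy = [add_noise(img, NoiseSpec(sigma_frac_range=(0.3, 0.3)), seed=i)
                 for i, img in enumerate(clean)]
        scores_noisy = [brisque_score(brisque_features(img), scorer) for img in noisy]
        assert all(0 <= s <= 100 for s in scores_clean + scores_noisy)
        assert np.mean(scores_noisy) > np.mean(scores_clean)


class TestStatTests:
    def test_identical_pairs_give_t_zero_p_one(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_nonzero_difference_signalled(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_unit_shift_detected_at_n_30(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        res = paired_t_test(x + 1.0 + rng.normal(0, 0.5, 30), x)
        assert res.significant and res.alpha == 0.05

    def test_ks_normality_type_one_calibration(self):
        """On true N(0,1) samples p > 0.05 in at least 90% of seeds."""
        keep = [ks_normality(np.random.default_rng(s).normal(0, 1, 500)).p_value > 0.05
                for s in range(100)]
        assert np.mean(keep) >= 0.90

    def test_ks_rejects_exponential(self):
        res = ks_normality(np.random.default_rng(0).exponential(1.0, 500))
        assert res.p_value < 0.05

    def test_dagostino_wrapper(self):
        res = dagostino_normality(np.random.default_rng(0).normal(0, 1, 500))
        assert res.test.startswith("D'Agostino") and res.alpha == 0.01


def test_evaluate_image_report_structure(phantom_and_rois):
    img, rois = phantom_and_rois
    noisy = add_noise(img, NoiseSpec(sigma_frac_range=(0.3, 0.3)), seed=0)
    rep = evaluate_image(noisy, rois, with_noise_map=True)
    assert set(rep.regions) == {"vessel_wall", "csf", "parenchyma"}
    assert rep.noise_map is not None and rep.brisque is None
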
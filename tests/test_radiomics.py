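"""Radiomic features against brute-force oracles, wavelet identities, Lin's CCC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vwdenoise.phantom import generate_phantom
from vwdenoise.radiomics import (RadiomicsConfig, all_texture_features, discretise,
                                 extract_feature_table, feature_class,
                                 first_order_features, glcm_matrix, glrlm_matrix,
                                 lin_ccc, reproducibility_report, texture_features,
                                 wavelet_subbands)

from conftest import small_phantom_spec

DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_glcm(labels, n_levels, direction, distance=1):
    """Direct pixel-pair enumeration (symmetric, unnormalised)."""
    H, W = labels.shape
    P = np.zeros((n_levels, n_levels))
    dy, dx = direction[0] * distance, direction[1] * distance
    for y in range(H):
        for x in range(W):
            yy, xx = y + dy, x + dx
            if 0 <= yy < H and 0 <= xx < W and labels[y, x] > 0 and labels[yy, xx] > 0:
                P[labels[y, x] - 1, labels[yy, xx] - 1] += 1
                P[labels[yy, xx] - 1, labels[y, x] - 1] += 1
    return P


def brute_glrlm(labels, n_levels, direction):
    """Direct maximal-run enumeration along a direction."""
    H, W = labels.shape
    R = np.zeros((n_levels, max(H, W)))
    dy, dx = direction
    seen = set()
    for y in range(H):
        for x in range(W):
            py, px = y - dy, x - dx
            if 0 <= py < H and 0 <= px < W:
                continue  # not the start of a line
            ly, lx, run_val, run_len = y, x, 0, 0
            while 0 <= ly < H and 0 <= lx < W:
                v = labels[ly, lx]
                if v == run_val:
                    run_len += 1
                else:
                    if run_val > 0:
                        R[run_val - 1, run_len - 1] += 1
                    run_val, run_len = v, 1
                ly, lx = ly + dy, lx + dx
            if run_val > 0:
                R[run_val - 1, run_len - 1] += 1
    return R


def brute_ccc(x, y):
    """Direct evaluation of the concordance moment formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    vx = sum((v - mx) ** 2 for v in x) / n
    vy = sum((v - my) ** 2 for v in y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * cov / (vx + vy + (mx - my) ** 2)


# ---------------------------------------------------------------------------
# discretisation and first-order
# ---------------------------------------------------------------------------

class TestDiscretise:
    def test_single_bin_labels_everything_one(self):
        arr = np.random.default_rng(0).normal(0, 1, (10, 10))
        assert (discretise(arr, np.ones((10, 10), dtype=bool), 1) == 1).all()

    def test_exact_partition_of_four_values(self):
        arr = np.array([[0.0, 1.0], [2.0, 3.0]])
        labels = discretise(arr, np.ones((2, 2), dtype=bool), 4)
        assert sorted(labels.ravel()) == [1, 2, 3, 4]

    def test_uniform_values_fill_bins_evenly(self):
        arr = np.random.default_rng(1).uniform(0, 1, (100, 100))
        labels = discretise(arr, np.ones((100, 100), dtype=bool), 8)
        freq = np.bincount(labels.ravel(), minlength=9)[1:] / 10_000
        assert np.allclose(freq, 1 / 8, atol=0.02)

    def test_constant_roi_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            discretise(np.ones((10, 10)), np.ones((10, 10), dtype=bool), 4)


class TestFirstOrder:
    def test_constant_roi(self):
        f = first_order_features(np.full((10, 10), 5.0), np.ones((10, 10), dtype=bool))
        assert f["mean"] == 5.0 and f["variance"] == 0.0
        assert f["range"] == 0.0 and f["uniformity"] == 1.0 and f["entropy"] == 0.0

    def test_hand_computed_values(self):
        arr = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (4, 1))
        f = first_order_features(arr, np.ones((4, 4), dtype=bool))
        assert f["mean"] == 2.5
        assert f["range"] == 3.0
        assert f["energy"] == pytest.approx(4 * 30.0)  # four rows of {1,2,3,4}
        assert abs(f["skewness"]) < 1e-12  # symmetric histogram

    def test_exactly_18_features(self):
        f = first_order_features(np.random.default_rng(0).normal(0, 1, (10, 10)),
                                 np.ones((10, 10), dtype=bool))
        assert len(f) == 18


# ---------------------------------------------------------------------------
# texture matrices vs oracles
# ---------------------------------------------------------------------------

class TestTextureMatrices:
    def test_glcm_two_by_two_example(self):
        g = np.array([[1, 1], [2, 2]], dtype=np.int32)
        P = glcm_matrix(g, 2, (0, 1), normalise=False)
        assert P[0, 0] == 2 and P[1, 1] == 2 and P[0, 1] == 0

    def test_glcm_probability_sums_to_one(self):
        g = discretise(np.random.default_rng(0).normal(0, 1, (20, 20)),
                       np.ones((20, 20), dtype=bool), 8)
        for d in DIRECTIONS:
            assert glcm_matrix(g, 8, d).sum() == pytest.approx(1.0)

    def test_constant_grid_has_single_full_runs(self):
        g = np.full((4, 4), 3, dtype=np.int32)
        R = glrlm_matrix(g, 4, (0, 1))
        assert R[2, 3] == 4 and R.sum() == 4  # one length-4 run per row

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_glcm_matches_brute_force_on_random_grids(self, direction):
        rng = np.random.default_rng(12)
        for _ in range(25):
            h, w = rng.integers(2, 7, 2)
            levels = int(rng.integers(2, 5))
            g = rng.integers(1, levels + 1, (h, w)).astype(np.int32)
            g[rng.random((h, w)) < 0.2] = 0  # holes outside the ROI
            ours = glcm_matrix(g, levels, direction, normalise=False)
            assert np.array_equal(ours, brute_glcm(g, levels, direction))

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_glrlm_matches_brute_force_on_random_grids(self, direction):
        rng = np.random.default_rng(34)
        for _ in range(25):
            h, w = rng.integers(2, 7, 2)
            levels = int(rng.integers(2, 5))
            g = rng.integers(0, levels + 1, (h, w)).astype(np.int32)
            ours = glrlm_matrix(g, levels, direction)
            theirs = brute_glrlm(g, levels, direction)
            assert np.array_equal(ours[:, : theirs.shape[1]], theirs)

    def test_family_sizes_total_75(self, phantom_and_rois):
        img, _ = phantom_and_rois
        roi = (12, 12, 40, 40)
        labelled = discretise(img.pixels, np.zeros_like(img.pixels, dtype=bool) |
                              _box_mask(img.shape, roi), 32)
        sizes = {fam: len(texture_features(labelled, fam)) for fam in
                 ("glcm", "glrlm", "glszm", "ngtdm", "gldm")}
        assert sizes == {"glcm": 24, "glrlm": 16, "glszm": 16, "ngtdm": 5, "gldm": 14}
        assert sum(sizes.values()) == 75

    def test_degenerate_single_level_emits_zeros_with_warning(self):
        g = np.ones((6, 6), dtype=np.int32)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            f = texture_features(g, "ngtdm")
        assert all(np.isfinite(v) for v in f.values())

    def test_shift_invariance_of_texture_features(self, phantom_and_rois):
        """Adding a constant to the raw image leaves all texture features unchanged."""
        img, _ = phantom_and_rois
        mask = _box_mask(img.shape, (12, 12, 24, 24))
        a = all_texture_features(img.pixels, mask)
        b = all_texture_features(img.pixels + 100.0, mask)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k


def _box_mask(shape, box):
    m = np.zeros(shape, dtype=bool)
    r, c, h, w = box
    m[r : r + h, c : c + w] = True
    return m


# ---------------------------------------------------------------------------
# wavelets
# ---------------------------------------------------------------------------

class TestWavelets:
    def test_constant_image_has_zero_detail_bands(self):
        bands = wavelet_subbands(np.full((32, 32), 4.0))
        for name in ("LH", "HL", "HH"):
            assert np.allclose(bands[name], 0.0)

    def test_energy_conservation(self):
        arr = np.random.default_rng(0).normal(0, 1, (64, 64))
        bands = wavelet_subbands(arr)
        total = sum(np.sum(b ** 2) for b in bands.values())
        assert abs(total - np.sum(arr ** 2)) < 1e-8 * np.sum(arr ** 2)

    def test_impulse_hits_one_coefficient_per_band(self):
        arr = np.zeros((16, 16))
        arr[0, 0] = 1.0
        for band in wavelet_subbands(arr).values():
            assert np.count_nonzero(band) == 1

    def test_odd_sides_rejected(self):
        with pytest.raises(ValueError, match="even"):
            wavelet_subbands(np.zeros((15, 16)))


# ---------------------------------------------------------------------------
# feature table and CCC
# ---------------------------------------------------------------------------

class TestFeatureTable:
    def test_column_count_and_classes(self, phantom_and_rois):
        table = extract_feature_table([phantom_and_rois[0]], (12, 12, 40, 40))
        assert table.shape == (1, 465)
        counts = table.columns.map(feature_class).value_counts().to_dict()
        assert counts == {"wavelet": 372, "texture": 75, "first_order": 18}

    def test_duplicate_images_give_identical_rows(self, phantom_and_rois):
        img = phantom_and_rois[0]
        table = extract_feature_table([img, img, img], (12, 12, 40, 40))
        assert len(table) == 3
        assert np.array_equal(table.iloc[0].to_numpy(), table.iloc[2].to_numpy())


class TestLinCcc:
    def test_perfect_concordance(self):
        assert lin_ccc([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]) == 1.0

    def test_perfect_reversal(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        assert lin_ccc(x, -x) == -1.0

    def test_against_direct_formula(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.1, 2.1, 2.9, 4.2]
        assert lin_ccc(np.array(x), np.array(y)) == pytest.approx(brute_ccc(x, y), abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            lin_ccc(np.ones(5), np.ones(5))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20),
           st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_lin_inequality(self, xs, seed):
        x = np.asarray(xs)
        y = x + np.random.default_rng(seed).normal(0, 1.0, x.size)
        if x.var() == 0 and y.var() == 0:
            return
        ccc = lin_ccc(x, y)
        assert ccc == pytest.approx(lin_ccc(y, x), abs=1e-12)
        if x.var() > 0 and y.var() > 0:
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc) <= abs(r) + 1e-9


class TestReproducibilityReport:
    def _table(self, rng, n=6):
        cols = {"firstorder_mean": rng.normal(0, 1, n),
                "glcm_contrast": rng.normal(5, 2, n),
                "wavelet-HH_glcm_contrast": rng.normal(1, 1, n)}
        return pd.DataFrame(cols)

    def test_identical_tables_are_fully_reproducible(self):
        t = self._table(np.random.default_rng(0))
        rep = reproducibility_report(t, t.copy())
        assert (rep.per_feature["ccc"] == 1.0).all()
        assert rep.per_feature["reproducible"].all()

    def test_heavy_noise_destroys_concordance(self):
        rng = np.random.default_rng(1)
        t = self._table(rng, n=30)
        noisy = t + rng.normal(0, 100, t.shape)
        rep = reproducibility_report(t, noisy)
        assert abs(rep.per_feature["ccc"]).max() < 0.5
        assert rep.per_feature["reproducible"].sum() == 0

    def test_summary_classes(self):
        t = self._table(np.random.default_rng(2))
        rep = reproducibility_report(t, t.copy())
        assert set(rep.summary.index) == {"first_order", "texture", "wavelet"}
        assert (rep.summary["pct_reproducible"] == 100.0).all()

    def test_mismatched_columns_rejected(self):
        t = self._table(np.random.default_rng(3))
        with pytest.raises(ValueError, match="column"):
            reproducibility_report(t, t.rename(columns={"glcm_contrast": "x"}))
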
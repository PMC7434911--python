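"""Radiomic feature extraction and reproducibility analysis.

Per image the extractor computes, on a fixed parenchyma ROI:

* 18 first-order intensity/histogram statistics;
* 75 texture features from five grey-level matrix families — co-occurrence
  (GLCM, 24), run length (GLRLM, 16), size zone (GLSZM, 16), neighbouring
  grey tone difference (NGTDM, 5) and dependence (GLDM, 14);
* the same 93 features on each of the four single-level Haar wavelet
  sub-bands (LL, LH, HL, HH), 372 in all,

for a 465-column feature table.  Reproducibility between two conditions is
quantified per feature with Lin's concordance correlation coefficient (CCC),
a feature counting as reproducible when CCC > 0.8, and summarised per class
(first-order / texture / wavelet) as mean +- sd and reproducible fractions.

Grey levels are discretised to a fixed bin count (default 32, equal width
over the ROI range), which makes every texture feature invariant to adding a
constant to the raw image.  Degenerate single-level ROIs yield 0 for features
whose formula divides by zero, with a warning, so tables stay rectangular.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage

from .phantom import GrayImage, roi_mask

WAVELET_BANDS = ("LL", "LH", "HL", "HH")
TEXTURE_FAMILIES = ("glcm", "glrlm", "glszm", "ngtdm", "gldm")

# distance-1 offsets for the four 2-D GLCM / GLRLM directions (0, 45, 90, 135 deg)
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class RadiomicsConfig:
    """Extraction settings: bin count, GLCM geometry, wavelet basis."""

    bins: int = 32
    glcm_distance: int = 1
    wavelet: str = "haar"

    def __post_init__(self):
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.float64)


def discretise(image, roi, bins: int) -> np.ndarray:
    """Equal-width binning over the ROI's [min, max]; labels 1..bins, 0 outside."""
    arr = _pixels(image)
    mask = roi_mask(roi, arr.shape)
    values = arr[mask]
    if values.size == 0:
        raise ValueError("empty ROI")
    lo, hi = float(values.min()), float(values.max())
    labels = np.zeros(arr.shape, dtype=np.int32)
    if bins == 1:
        labels[mask] = 1
        return labels
    if hi == lo:
        raise ValueError("constant ROI cannot be discretised into more than one bin")
    binned = np.floor((arr[mask] - lo) / (hi - lo) * bins).astype(np.int32) + 1
    labels[mask] = np.clip(binned, 1, bins)
    return labels


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------

def first_order_features(image, roi, bins: int = 32, pixel_spacing: float = 1.0) -> OrderedDict:
    """18 first-order statistics of the ROI intensities and their histogram."""
    arr = _pixels(image)
    x = arr[roi_mask(roi, arr.shape)].astype(np.float64)
    if x.size < 10:
        raise ValueError("ROI must contain at least 10 pixels")
    mean = float(x.mean())
    var = float(x.var())
    m2 = var
    if m2 > 0:
        skew = float(np.mean((x - mean) ** 3)) / m2 ** 1.5
        kurt = float(np.mean((x - mean) ** 4)) / m2 ** 2
    else:
        skew, kurt = 0.0, 0.0
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if np.ptp(x) > 0:
        hist, _ = np.histogram(x, bins=bins, range=(x.min(), x.max()))
    else:
        hist = np.array([x.size])
    p = hist[hist > 0] / x.size
    f = OrderedDict()
    f["energy"] = float(np.sum(x * x))
    f["total_energy"] = f["energy"] * pixel_spacing ** 2
    f["entropy"] = float(-np.sum(p * np.log2(p)))
    f["minimum"] = float(x.min())
    f["percentile10"] = float(p10)
    f["percentile90"] = float(p90)
    f["maximum"] = float(x.max())
    f["mean"] = mean
    f["median"] = float(np.median(x))
    f["interquartile_range"] = float(p75 - p25)
    f["range"] = float(np.ptp(x))
    f["mean_absolute_deviation"] = float(np.mean(np.abs(x - mean)))
    f["robust_mean_absolute_deviation"] = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    f["root_mean_squared"] = float(np.sqrt(np.mean(x * x)))
    f["skewness"] = skew
    f["kurtosis"] = kurt
    f["variance"] = var
    f["uniformity"] = float(np.sum(p * p))
    return f


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------

def _warn_degenerate(family):
    warnings.warn(f"degenerate {family} input (single grey level); "
                  "undefined features emitted as 0", RuntimeWarning, stacklevel=3)


def glcm_matrix(labels: np.ndarray, n_levels: int, direction, distance: int = 1,
                symmetric: bool = True, normalise: bool = True) -> np.ndarray:
    """Grey-level co-occurrence counts for one direction."""
    dy, dx = direction[0] * distance, direction[1] * distance
    H, W = labels.shape
    a = labels[max(0, -dy) : H - max(0, dy), max(0, -dx) : W - max(0, dx)]
    b = labels[max(0, dy) : H + min(0, dy) or H, max(0, dx) : W + min(0, dx) or W]
    valid = (a > 0) & (b > 0)
    P = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(P, (a[valid] - 1, b[valid] - 1), 1.0)
    if symmetric:
        P = P + P.T
    if normalise and P.sum() > 0:
        P = P / P.sum()
    return P


def _glcm_features(P: np.ndarray) -> OrderedDict:
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(px * i))
    uy = float(np.sum(py * i))
    sx = float(np.sqrt(np.sum(px * (i - ux) ** 2)))
    sy = float(np.sqrt(np.sum(py * (i - uy) ** 2)))
    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(Ng, dtype=np.float64)
    p_diff = np.array([P[np.abs(I - J) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * Ng + 1, dtype=np.float64)
    p_sum = np.array([P[(I + J) == k].sum() for k in k_sum])
    eps = np.finfo(np.float64).eps

    f = OrderedDict()
    f["autocorrelation"] = float(np.sum(P * I * J))
    f["joint_average"] = ux
    f["cluster_prominence"] = float(np.sum(P * (I + J - ux - uy) ** 4))
    f["cluster_shade"] = float(np.sum(P * (I + J - ux - uy) ** 3))
    f["cluster_tendency"] = float(np.sum(P * (I + J - ux - uy) ** 2))
    f["contrast"] = float(np.sum(P * (I - J) ** 2))
    f["correlation"] = float((np.sum(P * I * J) - ux * uy) / (sx * sy)) if sx > 0 and sy > 0 else 1.0
    da = float(np.sum(p_diff * k_diff))
    f["difference_average"] = da
    nz = p_diff > 0
    f["difference_entropy"] = float(-np.sum(p_diff[nz] * np.log2(p_diff[nz])))
    f["difference_variance"] = float(np.sum(p_diff * (k_diff - da) ** 2))
    f["joint_energy"] = float(np.sum(P * P))
    pnz = P[P > 0]
    hxy = float(-np.sum(pnz * np.log2(pnz)))
    f["joint_entropy"] = hxy
    pxpy = np.outer(px, py)
    m = P > 0
    hxy1 = float(-np.sum(P[m] * np.log2(pxpy[m] + eps)))
    mj = pxpy > 0
    hxy2 = float(-np.sum(pxpy[mj] * np.log2(pxpy[mj])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    denom = max(hx, hy)
    f["imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    f["imc2"] = float(np.sqrt(1 - np.exp(-2 * max(hxy2 - hxy, 0.0)))) if hxy2 >= hxy else 0.0
    f["idm"] = float(np.sum(P / (1.0 + (I - J) ** 2)))
    f["idmn"] = float(np.sum(P / (1.0 + ((I - J) / Ng) ** 2)))
    f["id"] = float(np.sum(P / (1.0 + np.abs(I - J))))
    f["idn"] = float(np.sum(P / (1.0 + np.abs(I - J) / Ng)))
    off = I != J
    f["inverse_variance"] = float(np.sum(P[off] / (I[off] - J[off]) ** 2))
    f["maximum_probability"] = float(P.max())
    f["sum_average"] = float(np.sum(p_sum * k_sum))
    snz = p_sum > 0
    f["sum_entropy"] = float(-np.sum(p_sum[snz] * np.log2(p_sum[snz])))
    f["sum_squares"] = float(np.sum(P * (I - ux) ** 2))
    # maximal correlation coefficient: sqrt of the second-largest eigenvalue of
    # Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k)), on the present levels
    rows = px > 0
    cols = py > 0
    if rows.sum() > 1:
        A = P[np.ix_(rows, cols)] / px[rows, None]
        B = P[np.ix_(rows, cols)] / py[None, cols]
        ev = np.sort(np.abs(np.linalg.eigvals(A @ B.T)))
        f["mcc"] = float(np.sqrt(np.clip(ev[-2], 0, 1)))
    else:
        f["mcc"] = 1.0
    return f


def glrlm_matrix(labels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Grey-level run-length counts for one direction."""
    dy, dx = direction
    H, W = labels.shape
    R = np.zeros((n_levels, max(H, W)), dtype=np.float64)
    # enumerate maximal runs along the direction
    if (dy, dx) == (0, 1):
        lines = [labels[r, :] for r in range(H)]
    elif (dy, dx) == (-1, 0):
        lines = [labels[:, c] for c in range(W)]
    else:
        flipped = labels[::-1] if dy == -1 else labels
        lines = [np.diagonal(flipped if dx == 1 else flipped[:, ::-1], offset=o)
                 for o in range(-(H - 1), W)]
    for line in lines:
        n = len(line)
        start = 0
        while start < n:
            g = line[start]
            end = start
            while end + 1 < n and line[end + 1] == g:
                end += 1
            if g > 0:
                R[g - 1, end - start] += 1
            start = end + 1
    return R


def _series_features(M: np.ndarray, axis_values: np.ndarray, n_pixels: int,
                     kind: str) -> OrderedDict:
    """Shared feature set for run-length (kind='run') and size-zone (kind='zone')
    matrices M[g-1, s-1]."""
    Ns = float(M.sum())
    f = OrderedDict()
    names = {
        "run": ("short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
                "gray_level_nonuniformity_normalised", "run_length_nonuniformity",
                "run_length_nonuniformity_normalised", "run_percentage",
                "gray_level_variance", "run_variance", "run_entropy",
                "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
                "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
                "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis"),
        "zone": ("small_area_emphasis", "large_area_emphasis", "gray_level_nonuniformity",
                 "gray_level_nonuniformity_normalised", "size_zone_nonuniformity",
                 "size_zone_nonuniformity_normalised", "zone_percentage",
                 "gray_level_variance", "zone_variance", "zone_entropy",
                 "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
                 "small_area_low_gray_level_emphasis", "small_area_high_gray_level_emphasis",
                 "large_area_low_gray_level_emphasis", "large_area_high_gray_level_emphasis"),
    }[kind]
    if Ns == 0:
        return OrderedDict((n, 0.0) for n in names)
    g = np.arange(1, M.shape[0] + 1, dtype=np.float64)
    s = axis_values.astype(np.float64)
    G, S = np.meshgrid(g, s, indexing="ij")
    p = M / Ns
    mg = M.sum(axis=1)
    ms = M.sum(axis=0)
    mu_g = float(np.sum(p * G))
    mu_s = float(np.sum(p * S))
    pnz = p[p > 0]
    vals = (
        float(np.sum(M / S ** 2) / Ns),
        float(np.sum(M * S ** 2) / Ns),
        float(np.sum(mg ** 2) / Ns),
        float(np.sum(mg ** 2) / Ns ** 2),
        float(np.sum(ms ** 2) / Ns),
        float(np.sum(ms ** 2) / Ns ** 2),
        float(Ns / n_pixels),
        float(np.sum(p * (G - mu_g) ** 2)),
        float(np.sum(p * (S - mu_s) ** 2)),
        float(-np.sum(pnz * np.log2(pnz))),
        float(np.sum(M / G ** 2) / Ns),
        float(np.sum(M * G ** 2) / Ns),
        float(np.sum(M / (G ** 2 * S ** 2)) / Ns),
        float(np.sum(M * G ** 2 / S ** 2) / Ns),
        float(np.sum(M * S ** 2 / G ** 2) / Ns),
        float(np.sum(M * S ** 2 * G ** 2) / Ns),
    )
    return OrderedDict(zip(names, vals))


def glszm_matrix(labels: np.ndarray, n_levels: int) -> np.ndarray:
    """Grey-level size-zone counts; zones are 8-connected components per level."""
    max_zone = int((labels > 0).sum())
    S = np.zeros((n_levels, max(max_zone, 1)), dtype=np.float64)
    structure = np.ones((3, 3), dtype=bool)
    for g in range(1, n_levels + 1):
        comp, n_comp = ndimage.label(labels == g, structure=structure)
        if n_comp:
            sizes = np.bincount(comp.ravel())[1:]
            for size in sizes:
                S[g - 1, size - 1] += 1
    return S


def _neighbour_sums(labels: np.ndarray):
    """Sum and count of in-ROI 8-neighbour labels at each pixel."""
    vals = labels.astype(np.float64)
    inroi = (labels > 0).astype(np.float64)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    total = ndimage.convolve(vals * inroi, kernel, mode="constant")
    count = ndimage.convolve(inroi, kernel, mode="constant")
    return total, count


def ngtdm_features(labels: np.ndarray, n_levels: int) -> OrderedDict:
    """Neighbouring grey tone difference features (coarseness, contrast,
    busyness, complexity, strength)."""
    mask = labels > 0
    Np = int(mask.sum())
    total, count = _neighbour_sums(labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(count > 0, total / count, 0.0)
    valid = mask & (count > 0)
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    for g in range(1, n_levels + 1):
        sel = valid & (labels == g)
        n[g - 1] = sel.sum()
        s[g - 1] = np.abs(g - avg[sel]).sum()
    Nv = n.sum()
    if Nv == 0:
        _warn_degenerate("ngtdm")
        return OrderedDict((k, 0.0) for k in ("coarseness", "contrast", "busyness", "complexity", "strength"))
    p = n / Nv
    i = np.arange(1, n_levels + 1, dtype=np.float64)
    present = p > 0
    Ngp = int(present.sum())
    f = OrderedDict()
    denom = float(np.sum(p * s))
    f["coarseness"] = float(1.0 / denom) if denom > 0 else 1e6
    if Ngp > 1:
        Pi, Pj = np.meshgrid(p[present], p[present], indexing="ij")
        Ii, Ij = np.meshgrid(i[present], i[present], indexing="ij")
        f["contrast"] = float(np.sum(Pi * Pj * (Ii - Ij) ** 2) / (Ngp * (Ngp - 1)) * s.sum() / Nv)
        busy_den = float(np.sum(np.abs(Ii * Pi - Ij * Pj)))
        f["busyness"] = float(denom / busy_den) if busy_den > 0 else 0.0
        Si, Sj = np.meshgrid(s[present], s[present], indexing="ij")
        f["complexity"] = float(np.sum(np.abs(Ii - Ij) * (Pi * Si + Pj * Sj) / (Pi + Pj)) / Nv)
        stot = s.sum()
        f["strength"] = float(np.sum((Pi + Pj) * (Ii - Ij) ** 2) / stot) if stot > 0 else 0.0
    else:
        _warn_degenerate("ngtdm")
        f["contrast"] = 0.0
        f["busyness"] = 0.0
        f["complexity"] = 0.0
        f["strength"] = 0.0
    return f


def gldm_features(labels: np.ndarray, n_levels: int, alpha: int = 0) -> OrderedDict:
    """Grey-level dependence features with a distance-1 neighbourhood.

    A neighbour is dependent when its level differs by at most ``alpha``; the
    dependence size of a pixel is 1 + its dependent-neighbour count.
    """
    mask = labels > 0
    Np = int(mask.sum())
    dep = np.ones(labels.shape, dtype=np.int64)
    for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)):
        shifted = np.roll(labels, (dy, dx), axis=(0, 1))
        edge = np.ones(labels.shape, dtype=bool)
        if dy == 1:
            edge[0, :] = False
        elif dy == -1:
            edge[-1, :] = False
        if dx == 1:
            edge[:, 0] = False
        elif dx == -1:
            edge[:, -1] = False
        dep += (edge & mask & (shifted > 0) & (np.abs(shifted - labels) <= alpha)).astype(np.int64)
    max_dep = 9
    D = np.zeros((n_levels, max_dep), dtype=np.float64)
    np.add.at(D, (labels[mask] - 1, dep[mask] - 1), 1.0)
    Nz = float(D.sum())
    if Nz == 0:
        raise ValueError("empty ROI: no dependence counts")
    g = np.arange(1, n_levels + 1, dtype=np.float64)
    d = np.arange(1, max_dep + 1, dtype=np.float64)
    G, S = np.meshgrid(g, d, indexing="ij")
    p = D / Nz
    mg = D.sum(axis=1)
    md = D.sum(axis=0)
    mu_g = float(np.sum(p * G))
    mu_d = float(np.sum(p * S))
    pnz = p[p > 0]
    f = OrderedDict()
    f["small_dependence_emphasis"] = float(np.sum(D / S ** 2) / Nz)
    f["large_dependence_emphasis"] = float(np.sum(D * S ** 2) / Nz)
    f["gray_level_nonuniformity"] = float(np.sum(mg ** 2) / Nz)
    f["dependence_nonuniformity"] = float(np.sum(md ** 2) / Nz)
    f["dependence_nonuniformity_normalised"] = float(np.sum(md ** 2) / Nz ** 2)
    f["gray_level_variance"] = float(np.sum(p * (G - mu_g) ** 2))
    f["dependence_variance"] = float(np.sum(p * (S - mu_d) ** 2))
    f["dependence_entropy"] = float(-np.sum(pnz * np.log2(pnz)))
    f["low_gray_level_emphasis"] = float(np.sum(D / G ** 2) / Nz)
    f["high_gray_level_emphasis"] = float(np.sum(D * G ** 2) / Nz)
    f["small_dependence_low_gray_level_emphasis"] = float(np.sum(D / (G ** 2 * S ** 2)) / Nz)
    f["small_dependence_high_gray_level_emphasis"] = float(np.sum(D * G ** 2 / S ** 2) / Nz)
    f["large_dependence_low_gray_level_emphasis"] = float(np.sum(D * S ** 2 / G ** 2) / Nz)
    f["large_dependence_high_gray_level_emphasis"] = float(np.sum(D * S ** 2 * G ** 2) / Nz)
    return f


def texture_features(labelled: np.ndarray, family: str,
                     config: RadiomicsConfig | None = None) -> OrderedDict:
    """Features of one texture family on a discretised (labelled) ROI grid."""
    config = config or RadiomicsConfig()
    n_levels = config.bins
    if family not in TEXTURE_FAMILIES:
        raise ValueError(f"unknown texture family {family!r}")
    n_present = len(np.unique(labelled[labelled > 0]))
    if family == "glcm":
        if n_present < 2:
            _warn_degenerate("glcm")
        per_dir = [_glcm_features(glcm_matrix(labelled, n_levels, d, config.glcm_distance))
                   for d in _DIRECTIONS]
        return OrderedDict((k, float(np.mean([f[k] for f in per_dir]))) for k in per_dir[0])
    if family == "glrlm":
        Np = int((labelled > 0).sum())
        per_dir = []
        for d in _DIRECTIONS:
            R = glrlm_matrix(labelled, n_levels, d)
            per_dir.append(_series_features(R, np.arange(1, R.shape[1] + 1), Np, "run"))
        return OrderedDict((k, float(np.mean([f[k] for f in per_dir]))) for k in per_dir[0])
    if family == "glszm":
        Np = int((labelled > 0).sum())
        S = glszm_matrix(labelled, n_levels)
        return _series_features(S, np.arange(1, S.shape[1] + 1), Np, "zone")
    if family == "ngtdm":
        return ngtdm_features(labelled, n_levels)
    return gldm_features(labelled, n_levels)


def all_texture_features(image, roi, config: RadiomicsConfig | None = None) -> OrderedDict:
    """All 75 texture features, names prefixed by family."""
    config = config or RadiomicsConfig()
    labelled = discretise(image, roi, config.bins)
    out = OrderedDict()
    for family in TEXTURE_FAMILIES:
        for k, v in texture_features(labelled, family, config).items():
            out[f"{family}_{k}"] = v
    return out


# ---------------------------------------------------------------------------
# wavelets
# ---------------------------------------------------------------------------

def wavelet_subbands(image, wavelet: str = "haar") -> dict:
    """Single-level orthonormal 2-D DWT; bands at half resolution.

    Band naming follows the row/column filter order: the first letter is the
    filter applied along rows, the second along columns.
    """
    arr = _pixels(image)
    if arr.shape[0] % 2 or arr.shape[1] % 2:
        raise ValueError("image sides must be even for a half-size decomposition")
    cA, (cH, cV, cD) = pywt.dwt2(arr, wavelet, mode="periodization")
    return {"LL": cA, "LH": cH, "HL": cV, "HH": cD}


# ---------------------------------------------------------------------------
# feature table and concordance
# ---------------------------------------------------------------------------

def _halve_roi(roi, shape):
    """Map a ROI on the full image to the half-resolution wavelet grid."""
    if isinstance(roi, np.ndarray):
        H, W = roi.shape
        return roi[: H - H % 2, : W - W % 2].reshape(H // 2, 2, W // 2, 2).any(axis=(1, 3))
    r0, c0, nr, nc = roi
    return (r0 // 2, c0 // 2, max(nr // 2, 1), max(nc // 2, 1))


def extract_feature_table(images, roi, config: RadiomicsConfig | None = None,
                          ids=None) -> pd.DataFrame:
    """465-column feature table: 93 features on the image plus 93 per wavelet band.

    ``roi`` (a mask or a ``(row0, col0, n_rows, n_cols)`` box) is shared by
    every image, matching a study design where the same parenchyma ROI is
    drawn on all conditions of each subject.
    """
    config = config or RadiomicsConfig()
    rows = []
    for image in images:
        arr = _pixels(image)
        spacing = image.pixel_spacing if isinstance(image, GrayImage) else 1.0
        row = OrderedDict()
        for k, v in first_order_features(arr, roi, config.bins, spacing).items():
            row[f"firstorder_{k}"] = v
        for k, v in all_texture_features(arr, roi, config).items():
            row[k] = v
        bands = wavelet_subbands(arr, config.wavelet)
        half = _halve_roi(roi, arr.shape)
        for band in WAVELET_BANDS:
            barr = bands[band]
            for k, v in first_order_features(barr, half, config.bins, 2 * spacing).items():
                row[f"wavelet-{band}_firstorder_{k}"] = v
            for k, v in all_texture_features(barr, half, config).items():
                row[f"wavelet-{band}_{k}"] = v
        rows.append(row)
    table = pd.DataFrame(rows, index=ids if ids is not None else range(len(rows)))
    if not np.all(np.isfinite(table.to_numpy())):
        raise ValueError("non-finite radiomic features")
    return table


def lin_ccc(x, y, sample: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    ``2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` with
    population (1/n) moments by default; ``sample=True`` uses 1/(n-1).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    ddof = 1 if sample else 0
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=ddof), y.var(ddof=ddof)
    cov = np.sum((x - mx) * (y - my)) / (x.size - ddof)
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("zero denominator: both samples constant and equal")
    return float(2 * cov / denom)


def feature_class(name: str) -> str:
    """Table-3 style class of a feature column: first_order, texture or wavelet."""
    if name.startswith("wavelet-"):
        return "wavelet"
    if name.startswith("firstorder_"):
        return "first_order"
    return "texture"


@dataclass
class CccReport:
    """Per-feature concordance between two conditions plus per-class summaries."""

    per_feature: pd.DataFrame  # index: feature; columns: ccc, reproducible, feature_class
    summary: pd.DataFrame      # index: class; mean, sd, n_features, n_reproducible, pct_reproducible
    threshold: float = 0.8


def reproducibility_report(tableA: pd.DataFrame, tableB: pd.DataFrame,
                           threshold: float = 0.8) -> CccReport:
    """Per-feature Lin's CCC between matched rows of two feature tables.

    Features with a degenerate denominator (both conditions constant) get
    CCC 1 when identical and 0 otherwise.  A feature is reproducible when
    CCC exceeds the threshold (default 0.8).
    """
    if list(tableA.columns) != list(tableB.columns):
        raise ValueError("feature tables must share an identical column set")
    if len(tableA) != len(tableB):
        raise ValueError("feature tables must have matched rows")
    records = []
    for col in tableA.columns:
        x = tableA[col].to_numpy()
        y = tableB[col].to_numpy()
        try:
            ccc = lin_ccc(x, y)
        except ValueError:
            ccc = 1.0 if np.allclose(x, y) else 0.0
        records.append((col, ccc, ccc > threshold, feature_class(col)))
    per_feature = pd.DataFrame(records, columns=["feature", "ccc", "reproducible", "feature_class"])
    per_feature = per_feature.set_index("feature")
    rows = []
    for cls, grp in per_feature.groupby("feature_class"):
        rows.append({
            "feature_class": cls,
            "mean": grp["ccc"].mean(),
            "sd": grp["ccc"].std(ddof=1),
            "n_features": len(grp),
            "n_reproducible": int(grp["reproducible"].sum()),
            "pct_reproducible": 100.0 * grp["reproducible"].mean(),
        })
    summary = pd.DataFrame(rows).set_index("feature_class")
    return CccReport(per_feature=per_feature, summary=summary, threshold=threshold)
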
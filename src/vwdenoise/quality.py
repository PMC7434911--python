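"""No-reference image-quality metrics and the associated statistics.

Pixel-aligned references do not exist for the clinical problem this package
models, so quality is measured without one:

* ROI-based noise and SNR: at the vessel wall the signal is the peak wall
  intensity and the noise is the standard deviation inside the lumen
  (``SNR = peak_wall / sigma_lumen``); for CSF and parenchyma both moments
  come from the ROI itself (``SNR = mean / std``).
* blockwise noise maps (default 5x5 tiles of local standard deviation);
* BRISQUE natural-scene statistics (36 MSCN-based features over two scales),
  with a self-contained scorer fitted to a pristine corpus in place of an
  externally trained regressor;
* paired-t and Kolmogorov-Smirnov tests at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.special import gamma as _gamma

from .phantom import GrayImage, RoiSet, roi_mask


class UndefinedSNRError(ArithmeticError):
    """Raised when the ROI noise is zero and SNR would be infinite."""


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.float64)


def _roi_values(arr, roi) -> np.ndarray:
    return arr[roi_mask(roi, arr.shape)]


def snr_vessel_wall(image, wall_roi, lumen_roi, peak: str = "max"):
    """Vessel-wall SNR: peak wall intensity over lumen standard deviation.

    ``peak='p99'`` uses the 99th percentile instead of the maximum, a more
    outlier-robust reading of "peak intensity".
    Returns ``(signal, noise, snr)``.
    """
    arr = _pixels(image)
    wall = _roi_values(arr, wall_roi)
    lumen = _roi_values(arr, lumen_roi)
    if wall.size == 0 or lumen.size < 4:
        raise ValueError("wall ROI must be non-empty and lumen ROI >= 4 pixels")
    signal = float(np.percentile(wall, 99)) if peak == "p99" else float(wall.max())
    noise = float(lumen.std(ddof=1))
    if noise == 0:
        raise UndefinedSNRError("lumen standard deviation is zero; SNR undefined")
    return signal, noise, signal / noise


def snr_region(image, roi):
    """Region SNR: ROI mean over ROI standard deviation; ``(signal, noise, snr)``."""
    values = _roi_values(_pixels(image), roi)
    if values.size < 4:
        raise ValueError("ROI must contain at least 4 pixels")
    signal = float(values.mean())
    noise = float(values.std(ddof=1))
    if noise == 0:
        raise UndefinedSNRError("ROI standard deviation is zero; SNR undefined")
    return signal, noise, signal / noise


@dataclass
class NoiseMap:
    """Grid of per-window sample standard deviations."""

    values: np.ndarray
    window: int = 5

    def __post_init__(self):
        if (self.values < 0).any():
            raise ValueError("noise map values must be non-negative")


def noise_map(image, window: int = 5, sliding: bool = False) -> NoiseMap:
    """Local standard deviation in ``window x window`` blocks.

    Non-overlapping tiles by default (edge remainders dropped); with
    ``sliding=True`` a dense same-size map via a moving window.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    arr = _pixels(image)
    if sliding:
        n = window * window
        m1 = ndimage.uniform_filter(arr, window)
        m2 = ndimage.uniform_filter(arr * arr, window)
        var = np.clip(m2 - m1 * m1, 0, None) * n / (n - 1)
        return NoiseMap(values=np.sqrt(var), window=window)
    H, W = arr.shape
    th, tw = H // window, W // window
    if th == 0 or tw == 0:
        raise ValueError("image smaller than one window")
    tiles = arr[: th * window, : tw * window].reshape(th, window, tw, window)
    return NoiseMap(values=tiles.std(axis=(1, 3), ddof=1), window=window)


# ---------------------------------------------------------------------------
# BRISQUE: MSCN statistics -> 36 features -> corpus-based score
# ---------------------------------------------------------------------------

_GAM_GRID = np.arange(0.2, 10.0, 0.001)
_R_GAM = (_gamma(2.0 / _GAM_GRID) ** 2) / (_gamma(1.0 / _GAM_GRID) * _gamma(3.0 / _GAM_GRID))


def _fit_ggd(x: np.ndarray):
    """Moment-matched generalised Gaussian fit: (shape alpha, variance)."""
    m2 = float(np.mean(x * x))
    m1 = float(np.mean(np.abs(x)))
    if m2 <= 0 or m1 <= 0:
        raise ValueError("degenerate MSCN statistics (constant image?)")
    rho = m1 * m1 / m2
    alpha = float(_GAM_GRID[np.argmin((_R_GAM - rho) ** 2)])
    return alpha, m2


def _fit_aggd(x: np.ndarray):
    """Asymmetric GGD fit: (alpha, mean eta, left variance, right variance)."""
    left = x[x < 0]
    right = x[x > 0]
    if left.size == 0 or right.size == 0:
        raise ValueError("degenerate pairwise-product statistics")
    lsq = float(np.sqrt(np.mean(left * left)))
    rsq = float(np.sqrt(np.mean(right * right)))
    gammahat = lsq / rsq
    rhat = float(np.mean(np.abs(x))) ** 2 / float(np.mean(x * x))
    rhatnorm = rhat * (gammahat ** 3 + 1) * (gammahat + 1) / (gammahat ** 2 + 1) ** 2
    alpha = float(_GAM_GRID[np.argmin((_R_GAM - rhatnorm) ** 2)])
    eta = (rsq - lsq) * _gamma(2.0 / alpha) / _gamma(1.0 / alpha)
    return alpha, float(eta), lsq * lsq, rsq * rsq


def _mscn(arr: np.ndarray, c: float = 1.0):
    sigma_blur = 7.0 / 6.0
    truncate = 3.0 / sigma_blur  # 7x7 support
    mu = ndimage.gaussian_filter(arr, sigma_blur, truncate=truncate)
    var = ndimage.gaussian_filter(arr * arr, sigma_blur, truncate=truncate) - mu * mu
    sigma = np.sqrt(np.clip(var, 0, None))
    return (arr - mu) / (sigma + c)


def brisque_features(image) -> np.ndarray:
    """36 natural-scene-statistics features over two scales.

    Intensities are rescaled to [0, 255]; the MSCN stabilising constant is 1
    on that scale.  Per scale: 2 GGD parameters of the MSCN map plus 4 AGGD
    parameters for each of 4 pairwise-product orientations (H, V, D1, D2).
    """
    arr = _pixels(image)
    if min(arr.shape) < 32:
        raise ValueError("image must be at least 32x32")
    ptp = np.ptp(arr)
    if ptp == 0:
        raise ValueError("constant image: BRISQUE features are degenerate")
    arr = 255.0 * (arr - arr.min()) / ptp
    feats = []
    for scale in range(2):
        if scale:
            h, w = arr.shape
            arr = arr[: h - h % 2, : w - w % 2].reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
        m = _mscn(arr)
        feats.extend(_fit_ggd(m))
        for shift in ((0, 1), (1, 0), (1, 1), (1, -1)):
            prod = m * np.roll(m, shift, axis=(0, 1))
            feats.extend(_fit_aggd(prod))
    out = np.asarray(feats, dtype=np.float64)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite BRISQUE features")
    return out


class BrisqueScorer:
    """Mahalanobis-to-pristine-corpus quality scorer.

    Fitted on the BRISQUE features of a corpus of clean images: features are
    standardised by the corpus moments and the covariance of the standardised
    features is estimated with Ledoit-Wolf shrinkage (well-conditioned even
    for small corpora).  The score of an image is a bounded, strictly
    monotone map of its Mahalanobis distance d to the corpus,
    ``100 * d / (d + 3 * median corpus distance)``, so it lies in [0, 100]
    with lower = better and never saturates.  Scores are comparable only
    within one corpus.
    """

    def __init__(self):
        self.mean_ = None
        self.std_ = None
        self.precision_ = None
        self.scale_ = None

    def fit(self, images_or_features) -> "BrisqueScorer":
        from sklearn.covariance import LedoitWolf

        rows = []
        for item in images_or_features:
            vec = np.asarray(item, dtype=np.float64) if np.ndim(item) == 1 else brisque_features(item)
            rows.append(vec)
        X = np.stack(rows)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 pristine images to fit the scorer")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.std_[self.std_ == 0] = 1.0
        Z = (X - self.mean_) / self.std_
        self.precision_ = LedoitWolf().fit(Z).precision_
        d = np.sqrt(np.einsum("ij,jk,ik->i", Z, self.precision_, Z))
        self.scale_ = float(np.median(d)) or 1.0
        return self

    def score(self, features: np.ndarray) -> float:
        if self.mean_ is None:
            raise ValueError("scorer has not been fitted")
        z = (np.asarray(features, dtype=np.float64) - self.mean_) / self.std_
        d = float(np.sqrt(z @ self.precision_ @ z))
        return float(np.clip(100.0 * d / (d + 3.0 * self.scale_), 0.0, 100.0))


def brisque_score(features, scorer) -> float:
    """Score a feature vector with a configured scorer; bounded to [0, 100]."""
    if scorer is None:
        raise ValueError("no BRISQUE scorer configured (fit a BrisqueScorer on clean images)")
    return scorer.score(features)


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

@dataclass
class StatTestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def paired_t_test(x, y, alpha: float = 0.05) -> StatTestResult:
    """Two-sided paired t test on matched samples."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            return StatTestResult("paired-t", 0.0, 1.0, x.size, alpha)
        raise ValueError("differences have zero variance but non-zero mean; t undefined")
    t, p = stats.ttest_rel(x, y)
    return StatTestResult("paired-t", float(t), float(p), x.size, alpha)


def ks_normality(x, alpha: float = 0.05) -> StatTestResult:
    """Kolmogorov-Smirnov test of standardised samples against N(0, 1)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample; normality test undefined")
    stat, p = stats.kstest((x - x.mean()) / sd, "norm")
    return StatTestResult("Kolmogorov-Smirnov", float(stat), float(p), x.size, alpha)


def dagostino_normality(x, alpha: float = 0.01) -> StatTestResult:
    """D'Agostino-Pearson omnibus normality test (skewness + kurtosis)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 20:
        raise ValueError("omnibus test needs at least 20 samples")
    stat, p = stats.normaltest(x)
    return StatTestResult("D'Agostino-Pearson", float(stat), float(p), x.size, alpha)


@dataclass
class QualityReport:
    """Per-region noise/SNR plus an optional BRISQUE score for one image."""

    regions: dict  # name -> {"signal":, "noise":, "snr":}
    brisque: float | None = None
    noise_map: NoiseMap | None = None

    def __post_init__(self):
        # SNR may legitimately be negative when a generative output drives a
        # region mean below zero; only the noise (a std) must be non-negative
        for name, row in self.regions.items():
            if row["noise"] < 0:
                raise ValueError(f"negative noise for region {name!r}")
        if self.brisque is not None and not 0 <= self.brisque <= 100:
            raise ValueError("BRISQUE score out of [0, 100]")


def evaluate_image(image, rois: RoiSet, scorer: BrisqueScorer | None = None,
                   with_noise_map: bool = False) -> QualityReport:
    """Standard per-image quality readout over the three reported regions."""
    regions = {}
    s, n, r = snr_vessel_wall(image, rois["vessel_wall"], rois["lumen"])
    regions["vessel_wall"] = {"signal": s, "noise": n, "snr": r}
    for name in ("csf", "parenchyma"):
        s, n, r = snr_region(image, rois[name])
        regions[name] = {"signal": s, "noise": n, "snr": r}
    score = scorer.score(brisque_features(image)) if scorer is not None else None
    nmap = noise_map(image) if with_noise_map else None
    return QualityReport(regions=regions, brisque=score, noise_map=nmap)
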
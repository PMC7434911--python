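"""Artificial corruption of clean MR images.

Two corruption routes are provided:

* additive zero-mean Gaussian noise whose standard deviation is drawn as a
  fraction of the image's arithmetic mean (default 25-35%, the range found to
  train the best denoiser), optionally Rician or spatially non-uniform; and
* k-space undersampling with a variable-density Poisson-disk mask followed by
  zero-filled reconstruction, the conventional compressed-sensing baseline.

Calibration utilities estimate the noise level from an air region of interest
and test its normality with the D'Agostino-Pearson omnibus test, the check
that justifies modelling the corruption as Gaussian in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .phantom import GrayImage, roi_mask


@dataclass
class NoiseSpec:
    """Additive-noise recipe.

    ``sigma_frac_range``: the per-image noise standard deviation is drawn
    uniformly from this range, expressed as a fraction of the image's
    arithmetic mean.  ``inhomogeneity`` optionally modulates sigma by a smooth
    multiplicative field ``1 + strength * f`` (``f`` zero-mean, unit-std,
    Gaussian-correlated with length ``scale`` pixels), emulating the spatially
    varying noise of parallel imaging.
    """

    mu: float = 0.0
    sigma_frac_range: tuple = (0.25, 0.35)
    family: str = "gaussian"  # "gaussian" | "rician"
    inhomogeneity: dict | None = None  # {"strength": float, "scale": px}
    clip: bool = False
    seed: int | None = None

    def __post_init__(self):
        lo, hi = self.sigma_frac_range
        if not 0 <= lo <= hi:
            raise ValueError("sigma_frac_range must satisfy 0 <= low <= high")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.family not in ("gaussian", "rician"):
            raise ValueError("family must be 'gaussian' or 'rician'")
        if self.family == "rician" and self.mu != 0:
            raise ValueError("Rician noise acts on the magnitude; mu must be 0")


def add_noise(image: GrayImage, spec: NoiseSpec, seed: int | None = None, return_sigma: bool = False):
    """Corrupt ``image`` according to ``spec``; seeded and unclipped by default."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    arr = image.pixels
    lo, hi = spec.sigma_frac_range
    frac = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    sigma = frac * float(arr.mean())
    if sigma == 0:
        out = arr.copy()
    else:
        sigma_map = sigma
        if spec.inhomogeneity:
            f = ndimage.gaussian_filter(rng.standard_normal(arr.shape), spec.inhomogeneity.get("scale", 8))
            f /= max(f.std(), 1e-12)
            sigma_map = sigma * np.clip(1.0 + spec.inhomogeneity.get("strength", 0.5) * f, 0.0, None)
        if spec.family == "gaussian":
            out = arr + spec.mu + sigma_map * rng.standard_normal(arr.shape)
        else:  # rician: magnitude of a complex signal with iid Gaussian parts
            re = arr + sigma_map * rng.standard_normal(arr.shape)
            im = sigma_map * rng.standard_normal(arr.shape)
            out = np.hypot(re, im)
    if spec.clip:
        out = np.clip(out, 0.0, None)
    result = GrayImage(pixels=out, pixel_spacing=image.pixel_spacing)
    return (result, sigma) if return_sigma else result


@dataclass
class NormalityResult:
    """Outcome of the D'Agostino-Pearson omnibus normality test."""

    statistic: float
    p_value: float
    n_samples: int
    alpha: float = 0.01

    @property
    def normal(self) -> bool:
        """Noise deemed Gaussian-modellable when p exceeds alpha (0.01)."""
        return self.p_value > self.alpha


def estimate_air_noise(image, air_roi):
    """Noise sigma (sample std) in an air ROI plus its normality test.

    The omnibus test combines skewness and kurtosis Z-scores into a chi-square
    statistic with 2 degrees of freedom; it is unreliable for tiny samples, so
    at least 20 pixels are required.
    """
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=np.float64)
    values = arr[roi_mask(air_roi, arr.shape)] if arr.ndim == 2 else arr.ravel()
    if values.size < 20:
        raise ValueError(f"air ROI has {values.size} pixels; at least 20 are required")
    if np.ptp(values) == 0:
        raise ValueError("air ROI is constant; noise moments are degenerate")
    sigma = float(values.std(ddof=1))
    stat, p = stats.normaltest(values)
    return sigma, NormalityResult(statistic=float(stat), p_value=float(p), n_samples=int(values.size))


@dataclass
class SamplingMask:
    """Boolean k-space sampling pattern, DC at the array centre."""

    mask: np.ndarray
    acceleration: float
    seed: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        h, w = self.mask.shape
        if not self.mask[h // 2, w // 2]:
            raise ValueError("the DC (centre) frequency must be sampled")

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


def poisson_disk_mask(shape, acceleration: float, seed: int = 0) -> SamplingMask:
    """Variable-density Poisson-disk sampling mask with a fully sampled centre.

    The exclusion radius grows linearly with distance from the k-space centre
    (denser low frequencies, the conventional compressed-sensing profile).
    The pattern is Hermitian-symmetric so that zero-filled reconstructions of
    real images stay real, and the sampled fraction is trimmed to the target
    1/acceleration.
    """
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    H, W = shape
    if acceleration == 1:
        return SamplingMask(mask=np.ones(shape, dtype=bool), acceleration=1.0, seed=seed)
    rng = np.random.default_rng(seed)
    target = int(round(H * W / acceleration))
    cy, cx = H // 2, W // 2

    # fully sampled calibration centre (~2% of samples, at least 6x6)
    half = max(3, int(round(np.sqrt(0.02 * target) / 2)))
    mask = np.zeros(shape, dtype=bool)
    mask[cy - half : cy + half, cx - half : cx + half] = True

    yy, xx = np.mgrid[:H, :W]
    rho = np.hypot(yy - cy, xx - cx) / np.hypot(cy, cx)  # 0 at DC, ~1 at corners

    # dart throwing with a radius that doubles from centre to edge; r0 set from
    # the empirical random-sequential-adsorption density ~0.7/r^2
    mean_density = target / (H * W)
    r0 = np.sqrt(0.7 / mean_density) / 1.5
    radius = r0 * (1.0 + rho)
    order = rng.permutation(H * W)
    cell = max(1.0, r0)
    gh, gw = int(np.ceil(H / cell)), int(np.ceil(W / cell))
    grid = [[[] for _ in range(gw)] for _ in range(gh)]
    pts = []

    def occupied(y, x, r):
        gy, gx = int(y / cell), int(x / cell)
        reach = int(np.ceil(r / cell))
        for ay in range(max(0, gy - reach), min(gh, gy + reach + 1)):
            for ax in range(max(0, gx - reach), min(gw, gx + reach + 1)):
                for (py, px) in grid[ay][ax]:
                    if (py - y) ** 2 + (px - x) ** 2 < r * r:
                        return True
        return False

    for idx in order:
        y, x = divmod(int(idx), W)
        if mask[y, x]:
            continue
        # sample only one half-plane; the mirror point is added alongside
        my, mx = (2 * cy - y) % H, (2 * cx - x) % W
        if (y, x) > (my, mx):
            continue
        r = radius[y, x]
        if occupied(y, x, r):
            continue
        for (py, px) in {(y, x), (my, mx)}:
            if not mask[py, px]:
                mask[py, px] = True
                grid[int(py / cell)][int(px / cell)].append((py, px))
                pts.append((py, px))

    # enforce exact Hermitian symmetry (the centre block edges are one-sided)
    mask |= np.roll(mask[::-1, ::-1], (1, 1), axis=(0, 1))

    # trim or top up (in mirror pairs) to hit the target fraction
    current = int(mask.sum())
    if current > target:
        ys, xs = np.nonzero(mask)
        removable = [(int(y), int(x)) for y, x in zip(ys, xs)
                     if not (cy - half <= y < cy + half and cx - half <= x < cx + half)]
        rng.shuffle(removable)
        seen = set()
        for (y, x) in removable:
            if current <= target:
                break
            if (y, x) in seen:
                continue
            my, mx = (2 * cy - y) % H, (2 * cx - x) % W
            seen.update({(y, x), (my, mx)})
            for (py, px) in {(y, x), (my, mx)}:
                if mask[py, px]:
                    mask[py, px] = False
                    current -= 1
    elif current < target:
        empty = np.flatnonzero(~mask.ravel())
        rng.shuffle(empty)
        for idx in empty:
            if current >= target:
                break
            y, x = divmod(int(idx), W)
            my, mx = (2 * cy - y) % H, (2 * cx - x) % W
            for (py, px) in {(y, x), (my, mx)}:
                if not mask[py, px]:
                    mask[py, px] = True
                    current += 1
    return SamplingMask(mask=mask, acceleration=float(acceleration), seed=seed)


def zero_fill_reconstruct(image: GrayImage, mask: SamplingMask, magnitude: bool = True) -> GrayImage:
    """FFT -> apply the sampling mask -> inverse FFT -> magnitude.

    A full mask reproduces the input to floating-point precision.  Because the
    mask is Hermitian-symmetric the reconstruction of a real image is real up
    to rounding; ``magnitude=False`` returns the signed real part, for which
    the operation is exactly linear and idempotent.
    """
    arr = image.pixels
    if mask.mask.shape != arr.shape:
        raise ValueError("mask shape does not match the image")
    k = np.fft.fftshift(np.fft.fft2(arr))
    recon = np.fft.ifft2(np.fft.ifftshift(k * mask.mask))
    out = np.abs(recon) if magnitude else recon.real
    return GrayImage(pixels=out, pixel_spacing=image.pixel_spacing)
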
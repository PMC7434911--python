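"""Synthetic vessel-wall MR phantoms and the datasets built from them.

The phantom emulates the contrast structure of a high-resolution
proton-density-weighted (HRPD) brain slice: a textured parenchyma disc,
bright CSF pockets, tube-like vessels rendered as bright wall rings around
dark lumina, and an air background at zero intensity.  The geometry is
deliberately simple — it exists so that every region of interest the
quantitative metrics need (vessel wall, lumen, CSF, parenchyma, air) is
available with exact ground truth.

Two dataset flavours are produced: pixel-aligned (corrupted, clean) pairs
for self-supervised training, and misaligned noisy/clean domains (small
random deformations between "acquisitions") for unsupervised training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

REGIONS = ("vessel_wall", "lumen", "csf", "parenchyma", "air")


class GeometryError(ValueError):
    """Raised when the requested phantom geometry cannot be realised."""


@dataclass
class GrayImage:
    """A 2-D float intensity raster with pixel-size metadata."""

    pixels: np.ndarray
    pixel_spacing: float = 0.4  # mm per pixel

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if min(self.pixels.shape) < 64:
            raise ValueError("image sides must be at least 64 pixels")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self):
        return self.pixels.shape


def roi_mask(roi, shape) -> np.ndarray:
    """Normalise a region spec (bool mask or (row0, col0, n_rows, n_cols) box)
    to a boolean mask congruent with ``shape``."""
    if isinstance(roi, np.ndarray):
        if roi.dtype != bool:
            raise ValueError("mask ROIs must be boolean arrays")
        if roi.shape != tuple(shape):
            raise ValueError("ROI mask shape does not match the image")
        return roi
    r0, c0, nr, nc = roi
    if r0 < 0 or c0 < 0 or r0 + nr > shape[0] or c0 + nc > shape[1] or nr <= 0 or nc <= 0:
        raise ValueError("box ROI out of image bounds")
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + nr, c0 : c0 + nc] = True
    return m


@dataclass
class RoiSet:
    """Named boolean region masks over one image."""

    masks: dict

    def __post_init__(self):
        for name in self.masks:
            if name not in REGIONS:
                raise ValueError(f"unknown region {name!r}; expected one of {REGIONS}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all region masks must share one shape")
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"region {name!r} is empty")
        if "lumen" in self.masks and "vessel_wall" in self.masks:
            if (self.masks["lumen"] & self.masks["vessel_wall"]).any():
                raise ValueError("lumen and vessel wall must be disjoint")

    def __getitem__(self, name) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name) -> bool:
        return name in self.masks

    @classmethod
    def from_boxes(cls, shape, boxes: dict) -> "RoiSet":
        return cls({name: roi_mask(box, shape) for name, box in boxes.items()})


@dataclass
class PhantomSpec:
    """Geometry and intensity recipe for one phantom.

    Intensities are in arbitrary units with the PD-like ordering
    air < lumen < parenchyma < wall enforced.  ``texture_correlation`` is the
    Gaussian correlation length (pixels) of the parenchyma texture field.
    """

    size: tuple = (300, 300)
    n_vessels: int = 3
    n_csf_pockets: int = 3
    air_intensity: float = 0.0
    lumen_intensity: float = 30.0
    parenchyma_intensity: float = 100.0
    csf_intensity: float = 160.0
    wall_intensity: float = 200.0
    texture_amplitude: float = 10.0
    texture_correlation: float = 3.0
    vessel_radius_range: tuple = (3.0, 7.0)
    pixel_spacing: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.size, int):
            self.size = (self.size, self.size)
        if min(self.size) < 64:
            raise ValueError("phantom sides must be at least 64 pixels")
        if not (self.air_intensity < self.lumen_intensity < self.parenchyma_intensity < self.wall_intensity):
            raise ValueError("intensities must satisfy air < lumen < parenchyma < wall")
        lo, hi = self.vessel_radius_range
        if not 0 < lo <= hi:
            raise ValueError("vessel radii must be positive and ordered")
        if self.n_vessels < 1 or self.n_csf_pockets < 0:
            raise ValueError("n_vessels must be >= 1, n_csf_pockets >= 0")
        if self.texture_amplitude < 0:
            raise ValueError("texture amplitude must be non-negative")


def _disk(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def generate_phantom(spec: PhantomSpec):
    """Render one phantom; returns ``(GrayImage, RoiSet)``.

    Deterministic given ``spec.seed``.  Raises :class:`GeometryError` when the
    requested vessels cannot be placed inside the brain disc.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    cy, cx = H / 2.0, W / 2.0
    brain_ry, brain_rx = 0.42 * H, 0.42 * W
    yy, xx = np.ogrid[:H, :W]
    brain = ((yy - cy) / brain_ry) ** 2 + ((xx - cx) / brain_rx) ** 2 <= 1.0

    # vessels: bright wall annulus around a dark lumen, mutually disjoint
    placed = []  # (cy, cx, lumen_r, outer_r)
    lo, hi = spec.vessel_radius_range
    for _ in range(spec.n_vessels):
        ok = False
        for _attempt in range(300):
            r = float(rng.uniform(lo, hi))
            wall = max(2.0, 0.6 * r)
            R = r + wall
            vy = float(rng.uniform(cy - brain_ry + R + 3, cy + brain_ry - R - 3))
            vx = float(rng.uniform(cx - brain_rx + R + 3, cx + brain_rx - R - 3))
            if ((vy - cy) / (brain_ry - R - 3)) ** 2 + ((vx - cx) / (brain_rx - R - 3)) ** 2 > 1.0:
                continue
            if all(np.hypot(vy - py, vx - px) > R + pR + 3 for py, px, pr, pR in placed):
                placed.append((vy, vx, r, R))
                ok = True
                break
        if not ok:
            raise GeometryError(
                f"could not place {spec.n_vessels} vessels of radius {lo}-{hi} in a {H}x{W} phantom"
            )

    lumen = np.zeros((H, W), dtype=bool)
    wall = np.zeros((H, W), dtype=bool)
    for vy, vx, r, R in placed:
        outer = _disk((H, W), (vy, vx), R)
        inner = _disk((H, W), (vy, vx), r)
        wall |= outer & ~inner
        lumen |= inner

    # CSF pockets: bright discs kept clear of the vessels
    csf = np.zeros((H, W), dtype=bool)
    vessel_zone = ndimage.binary_dilation(wall | lumen, iterations=3)
    for _ in range(spec.n_csf_pockets):
        for _attempt in range(300):
            r = float(rng.uniform(0.03, 0.06) * min(H, W))
            py = float(rng.uniform(cy - brain_ry + r + 3, cy + brain_ry - r - 3))
            px = float(rng.uniform(cx - brain_rx + r + 3, cx + brain_rx - r - 3))
            if ((py - cy) / (brain_ry - r - 3)) ** 2 + ((px - cx) / (brain_rx - r - 3)) ** 2 > 1.0:
                continue
            blob = _disk((H, W), (py, px), r)
            if not (blob & vessel_zone).any() and not (blob & csf).any():
                csf |= blob
                break

    image = np.full((H, W), spec.air_intensity, dtype=np.float64)
    image[brain] = spec.parenchyma_intensity
    if spec.texture_amplitude > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal((H, W)), spec.texture_correlation)
        tex *= spec.texture_amplitude / tex.std()
        image[brain] += tex[brain]
    image[csf] = spec.csf_intensity
    image[wall] = spec.wall_intensity
    image[lumen] = spec.lumen_intensity
    np.clip(image, 0.0, None, out=image)

    structure_zone = ndimage.binary_dilation(wall | lumen | csf, iterations=2)
    parenchyma = brain & ~structure_zone
    parenchyma &= ndimage.binary_erosion(brain, iterations=3)
    air = ~ndimage.binary_dilation(brain, iterations=2)

    rois = RoiSet({"vessel_wall": wall, "lumen": lumen, "csf": csf, "parenchyma": parenchyma, "air": air})
    return GrayImage(pixels=image, pixel_spacing=spec.pixel_spacing), rois


def deform(image: GrayImage, magnitude: float, seed: int = 0) -> GrayImage:
    """Apply a smooth random displacement field of the given mean magnitude.

    ``magnitude`` is the mean displacement-vector norm in pixels;
    ``magnitude=0`` returns the input unchanged.
    """
    if magnitude < 0:
        raise ValueError("deformation magnitude must be non-negative")
    if magnitude == 0:
        return GrayImage(pixels=image.pixels.copy(), pixel_spacing=image.pixel_spacing)
    rng = np.random.default_rng(seed)
    H, W = image.shape
    gh, gw = max(4, H // 16), max(4, W // 16)
    coarse = rng.standard_normal((2, gh, gw))
    disp = np.stack(
        [ndimage.zoom(coarse[i], (H / gh, W / gw), order=3, mode="reflect", grid_mode=True) for i in range(2)]
    )
    disp = ndimage.gaussian_filter(disp, sigma=(0, 2, 2))
    disp -= disp.mean(axis=(1, 2), keepdims=True)  # local deformation, no bulk shift
    norm = np.hypot(disp[0], disp[1]).mean()
    disp *= magnitude / max(norm, 1e-12)
    rows, cols = np.mgrid[:H, :W].astype(np.float64)
    warped = ndimage.map_coordinates(
        image.pixels, [rows + disp[0], cols + disp[1]], order=1, mode="reflect"
    )
    return GrayImage(pixels=warped, pixel_spacing=image.pixel_spacing)


@dataclass
class PairedDataset:
    """Pixel-aligned (corrupted, clean) pairs with per-pair provenance."""

    pairs: list  # [(GrayImage corrupted, GrayImage clean), ...]
    provenance: list = field(default_factory=list)  # [{"sigma":, "sigma_frac":, "seed":}, ...]
    rois: list | None = None

    def __post_init__(self):
        for noisy, clean in self.pairs:
            if noisy.shape != clean.shape:
                raise ValueError("corrupted and clean members must share a shape")

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]


@dataclass
class UnpairedDataset:
    """Independent noisy (A) and clean (B) domains; no pixel alignment."""

    domain_A: list  # noisy GrayImages
    domain_B: list  # clean GrayImages
    rois_A: list | None = None
    rois_B: list | None = None

    def __post_init__(self):
        if not self.domain_A or not self.domain_B:
            raise ValueError("both domains must be non-empty")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def make_paired_dataset(n: int, spec: PhantomSpec, noise_spec, seed: int = 0) -> PairedDataset:
    """``n`` independently drawn phantoms, each corrupted from its own clean member."""
    from .corruption import add_noise

    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = _child_seeds(seed, 2 * n)
    pairs, prov, rois = [], [], []
    for i in range(n):
        sp = PhantomSpec(**{**spec.__dict__, "seed": int(seeds[2 * i])})
        clean, roi = generate_phantom(sp)
        noisy, sigma = add_noise(clean, noise_spec, seed=int(seeds[2 * i + 1]), return_sigma=True)
        pairs.append((noisy, clean))
        prov.append({"sigma": sigma, "sigma_frac": sigma / max(clean.pixels.mean(), 1e-300),
                     "phantom_seed": int(seeds[2 * i]), "noise_seed": int(seeds[2 * i + 1])})
        rois.append(roi)
    return PairedDataset(pairs=pairs, provenance=prov, rois=rois)


def make_unpaired_dataset(nA: int, nB: int, spec: PhantomSpec, noise_spec,
                          deform_magnitude: float = 2.0, seed: int = 0) -> UnpairedDataset:
    """Domain A: deformed-then-corrupted phantoms; domain B: independent clean phantoms."""
    from .corruption import add_noise

    if nA < 1 or nB < 1:
        raise ValueError("nA and nB must be >= 1")
    seeds = _child_seeds(seed, 3 * nA + nB)
    A, rois_A = [], []
    for i in range(nA):
        sp = PhantomSpec(**{**spec.__dict__, "seed": int(seeds[3 * i])})
        clean, roi = generate_phantom(sp)
        warped = deform(clean, deform_magnitude, seed=int(seeds[3 * i + 1]))
        noisy = add_noise(warped, noise_spec, seed=int(seeds[3 * i + 2]))
        A.append(noisy)
        rois_A.append(roi)
    B, rois_B = [], []
    for j in range(nB):
        sp = PhantomSpec(**{**spec.__dict__, "seed": int(seeds[3 * nA + j])})
        clean, roi = generate_phantom(sp)
        B.append(clean)
        rois_B.append(roi)
    return UnpairedDataset(domain_A=A, domain_B=B, rois_A=rois_A, rois_B=rois_B)
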
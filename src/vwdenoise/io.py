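"""Reading and writing images, masks and dataset manifests.

Images travel as NIfTI (preserving pixel spacing) or 16-bit PNG; region
masks as per-region 8-bit PNG or NIfTI label maps; datasets as a directory
of images plus a ``manifest.csv``.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import GrayImage, PairedDataset, RoiSet

PNG16_MAX = 65535


def write_nifti(image: GrayImage, path) -> None:
    affine = np.diag([image.pixel_spacing, image.pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(image.pixels.astype(np.float32), affine), str(path))


def read_nifti(path) -> GrayImage:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    spacing = float(img.header.get_zooms()[0])
    return GrayImage(pixels=arr, pixel_spacing=spacing)


def write_png16(image: GrayImage, path, vmax: float | None = None) -> None:
    """Scale [0, vmax] (default image max) onto the 16-bit range."""
    arr = np.clip(image.pixels, 0, None)
    top = float(vmax if vmax is not None else max(arr.max(), 1e-12))
    iio.imwrite(str(path), np.clip(arr / top * PNG16_MAX, 0, PNG16_MAX).astype(np.uint16))


def read_png(path, pixel_spacing: float = 0.4) -> GrayImage:
    return GrayImage(pixels=np.asarray(iio.imread(str(path)), dtype=np.float64),
                     pixel_spacing=pixel_spacing)


def read_image(path, pixel_spacing: float = 0.4) -> GrayImage:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        return read_nifti(path)
    return read_png(path, pixel_spacing)


def write_mask_png(mask: np.ndarray, path) -> None:
    iio.imwrite(str(path), (mask.astype(np.uint8) * 255))


def write_rois(rois: RoiSet, directory, stem: str) -> None:
    directory = Path(directory)
    for name, mask in rois.masks.items():
        write_mask_png(mask, directory / f"{stem}_{name}.png")


def read_rois(directory, stem: str) -> RoiSet:
    directory = Path(directory)
    masks = {}
    for path in sorted(directory.glob(f"{stem}_*.png")):
        name = path.stem[len(stem) + 1 :]
        masks[name] = np.asarray(iio.imread(str(path))) > 0
    return RoiSet(masks)


def save_paired_dataset(dataset: PairedDataset, directory, fmt: str = "nii.gz") -> pd.DataFrame:
    """Write all pairs plus a manifest with noise provenance; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (noisy, clean) in enumerate(dataset):
        pc = directory / f"clean_{i:04d}.{fmt}"
        pn = directory / f"noisy_{i:04d}.{fmt}"
        if fmt == "png":
            top = max(clean.pixels.max(), noisy.pixels.max())
            write_png16(clean, pc, vmax=top)
            write_png16(noisy, pn, vmax=top)
        else:
            write_nifti(clean, pc)
            write_nifti(noisy, pn)
        prov = dataset.provenance[i] if i < len(dataset.provenance) else {}
        rows.append({"path_clean": pc.name, "path_noisy": pn.name,
                     "sigma": prov.get("sigma", np.nan), "seed": prov.get("noise_seed", -1)})
        if dataset.rois is not None:
            write_rois(dataset.rois[i], directory, f"roi_{i:04d}")
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def load_paired_dataset(directory) -> PairedDataset:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    pairs, prov, rois = [], [], []
    have_rois = True
    for _, row in manifest.iterrows():
        clean = read_image(directory / row["path_clean"])
        noisy = read_image(directory / row["path_noisy"])
        pairs.append((noisy, clean))
        prov.append({"sigma": row.get("sigma", np.nan), "noise_seed": int(row.get("seed", -1))})
        stem = f"roi_{len(pairs) - 1:04d}"
        if have_rois and list(directory.glob(f"{stem}_*.png")):
            rois.append(read_rois(directory, stem))
        else:
            have_rois = False
    return PairedDataset(pairs=pairs, provenance=prov, rois=rois if have_rois else None)
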
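"""Reading, writing and preparing paired image/mask data.

The pipeline is 2-D slice-based end to end: volumes (DICOM series or
NIfTI) are loaded only to extract individual sagittal sections, which are
then resampled and intensity-normalized. Masks travel as 8-bit PNG or
NIfTI uint8 rasters; datasets are described by a CSV manifest of
image/mask path pairs with a train/val/test split tag.

Conventions: arrays are row-major ``(row, col)`` with 0-based indexing;
the slice axis of a loaded volume is axis 0; the "median" sagittal slice
of an extent-``n`` volume is index ``n // 2``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import DataError, FormatError, InconsistencyError

__all__ = [
    "ImageSlice", "BinaryMask", "PairedDataset",
    "load_volume", "extract_sagittal_slice",
    "resample_slice", "resample_mask", "normalize_intensity",
    "read_image_png", "write_image_png", "read_mask_png", "write_mask_png",
    "write_nifti", "read_manifest", "write_manifest",
]

_MIN_DIM = 8


@dataclass
class ImageSlice:
    """A 2-D grayscale section with intensities intended to live in [0, 1]."""

    pixels: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise DataError("ImageSlice requires a 2-D array")
        if min(self.pixels.shape) < _MIN_DIM:
            raise DataError(f"slice smaller than {_MIN_DIM} px: {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("non-finite intensities in slice")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """A 2-D {0,1} label raster."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise DataError("BinaryMask requires a 2-D array")
        if not np.isin(arr, (0, 1)).all():
            raise DataError("mask values must be exactly 0 or 1")
        self.pixels = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PairedDataset:
    """Ordered (image, mask) pairs with per-pair split tags."""

    pairs: list[tuple[ImageSlice, BinaryMask]]
    split: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.split:
            self.split = ["train"] * len(self.pairs)
        if len(self.split) != len(self.pairs):
            raise DataError("split tags must match number of pairs")
        for img, msk in self.pairs:
            if img.pixels.shape != msk.pixels.shape:
                raise DataError(
                    f"image/mask shape mismatch: {img.pixels.shape} vs "
                    f"{msk.pixels.shape}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int) -> tuple[ImageSlice, BinaryMask]:
        return self.pairs[i]

    def subset(self, tag: str) -> "PairedDataset":
        sel = [p for p, s in zip(self.pairs, self.split) if s == tag]
        return PairedDataset(sel, [tag] * len(sel))

    def images(self) -> np.ndarray:
        """Stacked image batch of shape (n, 1, H, W)."""
        return np.stack([p[0].pixels for p in self.pairs])[:, None, :, :]

    def masks(self) -> np.ndarray:
        """Stacked mask batch of shape (n, 1, H, W), float."""
        return np.stack([p[1].pixels for p in self.pairs]
                        ).astype(np.float64)[:, None, :, :]


# ---------------------------------------------------------------------------
# volume loading

def load_volume(path: str, format: str) -> tuple[np.ndarray, str]:
    """Load a 3-D intensity array; returns ``(volume, provenance)``.

    ``format`` is ``"nifti"`` (a .nii/.nii.gz file) or ``"dicom-series"``
    (a directory of single-slice DICOM files). The slice axis is axis 0.
    Voxel spacing, when available, is recorded in the provenance string.
    """
    if format == "nifti":
        import nibabel as nib
        try:
            img = nib.load(path)
            data = np.asarray(img.get_fdata())
        except Exception as exc:  # nibabel raises various types
            raise FormatError(f"cannot read NIfTI file {path!r}: {exc}") from exc
        if data.ndim != 3:
            raise FormatError(f"{path!r}: expected a 3-D NIfTI volume, "
                              f"got ndim={data.ndim}")
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return data, f"nifti:{path} spacing={zooms}"
    if format == "dicom-series":
        import pydicom
        if not os.path.isdir(path):
            raise FormatError(f"DICOM series path {path!r} is not a directory")
        files = sorted(os.path.join(path, f) for f in os.listdir(path)
                       if not f.startswith("."))
        if not files:
            raise FormatError(f"no files in DICOM series directory {path!r}")
        slices = []
        for f in files:
            try:
                ds = pydicom.dcmread(f)
                arr = ds.pixel_array.astype(np.float64)
            except Exception as exc:
                raise FormatError(f"cannot read DICOM file {f!r}: {exc}") from exc
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            inter = float(getattr(ds, "RescaleIntercept", 0.0))
            order = getattr(ds, "InstanceNumber", None)
            slices.append((order if order is not None else len(slices),
                           arr * slope + inter, f))
        shapes = {s[1].shape for s in slices}
        if len(shapes) > 1:
            raise InconsistencyError(
                f"inconsistent slice dimensions in {path!r}: {sorted(shapes)}")
        slices.sort(key=lambda s: s[0])
        vol = np.stack([s[1] for s in slices])
        return vol, f"dicom-series:{path} nslices={len(slices)}"
    raise ValueError(f"unknown format {format!r}; use 'nifti' or 'dicom-series'")


def extract_sagittal_slice(volume: np.ndarray, index="median",
                           provenance: str = "") -> ImageSlice:
    """Take one section along the slice axis; ``"median"`` -> extent // 2."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise DataError("extract_sagittal_slice expects a 3-D volume")
    extent = volume.shape[0]
    if index == "median":
        index = extent // 2
    if not (0 <= int(index) < extent):
        raise IndexError(f"slice index {index} out of range [0, {extent})")
    return ImageSlice(volume[int(index)],
                      provenance=f"{provenance} slice={int(index)}".strip())


# ---------------------------------------------------------------------------
# resampling and normalization

def resample_slice(img: ImageSlice, target: tuple[int, int]) -> ImageSlice:
    """Bilinear resampling of an intensity slice to ``(height, width)``."""
    from skimage.transform import resize
    h, w = int(target[0]), int(target[1])
    if h < _MIN_DIM or w < _MIN_DIM:
        raise ValueError(f"target dimensions must be >= {_MIN_DIM}, got {target}")
    if (h, w) == img.pixels.shape:
        return ImageSlice(img.pixels.copy(), provenance=img.provenance)
    out = resize(img.pixels, (h, w), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return ImageSlice(out, provenance=f"{img.provenance} resampled={h}x{w}".strip())


def resample_mask(mask: BinaryMask, target: tuple[int, int]) -> BinaryMask:
    """Nearest-neighbour resampling of a mask; output stays in {0,1}."""
    from skimage.transform import resize
    h, w = int(target[0]), int(target[1])
    if h < _MIN_DIM or w < _MIN_DIM:
        raise ValueError(f"target dimensions must be >= {_MIN_DIM}, got {target}")
    out = resize(mask.pixels, (h, w), order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return BinaryMask(out.astype(np.uint8))


def normalize_intensity(img: ImageSlice, mode="minmax") -> ImageSlice:
    """Map intensities into [0, 1].

    ``mode="minmax"`` maps min -> 0 and max -> 1; a constant slice maps to
    all zeros. ``mode=("percentile", p_lo, p_hi)`` first clips at the
    given percentiles, then min-max rescales — robust to hot-spot
    outliers, the usual choice for PET slices with focal tracer uptake.
    """
    x = img.pixels
    if not np.all(np.isfinite(x)):
        raise DataError("cannot normalize non-finite intensities")
    if mode == "minmax":
        lo, hi = float(x.min()), float(x.max())
    elif isinstance(mode, tuple) and mode[0] == "percentile":
        p_lo, p_hi = float(mode[1]), float(mode[2])
        if not 0 <= p_lo < p_hi <= 100:
            raise ValueError(f"bad percentile bounds ({p_lo}, {p_hi})")
        lo, hi = (float(v) for v in np.percentile(x, (p_lo, p_hi)))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if hi <= lo:
        out = np.zeros_like(x)
    else:
        out = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return ImageSlice(out, provenance=img.provenance)


# ---------------------------------------------------------------------------
# raster and manifest I/O

def write_image_png(img: ImageSlice, path: str) -> None:
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_image_png(path: str) -> ImageSlice:
    try:
        arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    except Exception as exc:
        raise FormatError(f"cannot read PNG {path!r}: {exc}") from exc
    return ImageSlice(arr / 255.0, provenance=f"png:{path}")


def write_mask_png(mask: BinaryMask, path: str) -> None:
    Image.fromarray(mask.pixels * np.uint8(255), mode="L").save(path)


def read_mask_png(path: str) -> BinaryMask:
    try:
        arr = np.asarray(Image.open(path).convert("L"))
    except Exception as exc:
        raise FormatError(f"cannot read PNG {path!r}: {exc}") from exc
    return BinaryMask((arr > 127).astype(np.uint8))


def write_nifti(volume: np.ndarray, path: str) -> None:
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.asarray(volume), affine=np.eye(4)), path)


def write_manifest(rows: list[dict], path: str) -> None:
    """CSV manifest with columns image, mask, split."""
    pd.DataFrame(rows, columns=["image", "mask", "split"]).to_csv(path, index=False)


def read_manifest(path: str, root: str | None = None) -> PairedDataset:
    df = pd.read_csv(path)
    for col in ("image", "mask", "split"):
        if col not in df.columns:
            raise FormatError(f"manifest {path!r} missing column {col!r}")
    root = root if root is not None else os.path.dirname(os.path.abspath(path))
    pairs, split = [], []
    for _, row in df.iterrows():
        img = read_image_png(os.path.join(root, row["image"]))
        msk = read_mask_png(os.path.join(root, row["mask"]))
        pairs.append((img, msk))
        split.append(str(row["split"]))
    return PairedDataset(pairs, split)
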
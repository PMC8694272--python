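"""Synthetic low-contrast brain phantoms with a cortex-ribbon target.

Real FDG-PET sections show low contrast, low resolution and blurred
tissue boundaries, and the frontal cortex is a thin curved band with no
sharp edge against neighbouring tissue. The phantom reproduces that
statistical difficulty on a desk scale:

* the "brain" is an ellipse whose radius is perturbed by a few random
  low-frequency sinusoidal harmonics (a smooth, anatomically plausible
  deformation of the outline);
* the target "cortex ribbon" is a thin band hugging an arc of that
  deformed outline over a configurable angular span (the frontal
  sector), inset one pixel so it lies strictly inside the brain;
* the rendered slice is piecewise constant (background 0, interior
  tissue level, ribbon level ``tissue + contrast_gap``) degraded by a
  Gaussian blur and additive Gaussian noise, then clipped to [0, 1].

Everything is a pure function of ``(params, seed)``: per-instance
randomness comes from ``numpy.random.SeedSequence([params.seed,
instance_seed])`` so datasets are bit-reproducible. Gaussian noise is a
simplification of PET Poisson count statistics; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .data_io import BinaryMask, ImageSlice, PairedDataset
from .exceptions import GenerationError

__all__ = ["PhantomParams", "generate_mask", "render_slice",
           "generate_dataset", "split_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    """Knobs of the phantom population.

    ``brain_axes=None`` derives the ellipse semi-axes from the image size
    (0.40 and 0.32 of it). ``contrast_gap`` is the intensity difference
    between ribbon and interior tissue — the central difficulty dial:
    small gaps plus blur and noise make the ribbon boundary invisible to
    the eye, as in real PET.
    """

    image_size: int = 128
    brain_axes: tuple[float, float] | None = None
    ribbon_thickness: float = 7.0
    ribbon_angular_span: float = 2.1   # rad, ~120 deg frontal sector
    deformation_amplitude: float = 3.0  # px
    blur_sigma: float = 2.0
    noise_sigma: float = 0.05
    contrast_gap: float = 0.15
    tissue_level: float = 0.45
    seed: int = 0

    def axes(self) -> tuple[float, float]:
        if self.brain_axes is not None:
            return (float(self.brain_axes[0]), float(self.brain_axes[1]))
        return (0.40 * self.image_size, 0.32 * self.image_size)

    def validate(self) -> None:
        if self.image_size < 8:
            raise GenerationError("image_size must be >= 8")
        if self.ribbon_thickness < 1:
            raise GenerationError("ribbon_thickness must be >= 1 pixel")
        if not 0 < self.ribbon_angular_span <= 2 * np.pi:
            raise GenerationError("ribbon_angular_span must be in (0, 2*pi]")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise GenerationError("blur/noise sigmas must be >= 0")
        if not 0 < self.contrast_gap <= 1:
            raise GenerationError("contrast_gap must be in (0, 1]")


_N_HARMONICS = 3  # low-frequency outline harmonics k = 2, 3, 4


def _geometry(params: PhantomParams, instance_seed: int):
    """Per-instance deformed outline: returns (cy, cx, theta0, radius_fn).

    All instance variability (centre jitter, ribbon orientation jitter,
    outline harmonics) scales with ``deformation_amplitude`` so that a
    zero amplitude yields the exact centred, undeformed ellipse with the
    ribbon centred on the +y (anterior) direction.
    """
    params.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed) % (2**31), int(instance_seed), 0]))
    amp = float(params.deformation_amplitude)
    a, b = params.axes()
    c = (params.image_size - 1) / 2.0
    cy = c + rng.uniform(-0.3, 0.3) * amp
    cx = c + rng.uniform(-0.3, 0.3) * amp
    theta0 = np.pi / 2 + rng.uniform(-0.15, 0.15) * min(amp, 1.0)
    amps = rng.uniform(0.0, 1.0, _N_HARMONICS)
    s = amps.sum()
    amps = amp * amps / s if s > 0 else amps
    phases = rng.uniform(0.0, 2 * np.pi, _N_HARMONICS)

    def radius(theta: np.ndarray) -> np.ndarray:
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        for k, (ak, pk) in enumerate(zip(amps, phases), start=2):
            r = r + ak * np.cos(k * theta + pk)
        return r

    return cy, cx, theta0, radius


def _polar(params: PhantomParams, cy: float, cx: float):
    n = params.image_size
    rows, cols = np.mgrid[0:n, 0:n]
    dy = -(rows - cy)  # +y points up ("anterior")
    dx = cols - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return rho, theta


def generate_mask(params: PhantomParams, instance_seed: int) -> BinaryMask:
    """One cortex-ribbon ground-truth mask, deterministic in both seeds."""
    cy, cx, theta0, radius = _geometry(params, instance_seed)
    rho, theta = _polar(params, cy, cx)
    r_out = radius(theta) - 1.0  # 1 px inset keeps the ribbon inside the brain
    r_in = r_out - params.ribbon_thickness
    d = np.mod(theta - theta0 + np.pi, 2 * np.pi) - np.pi
    in_sector = np.abs(d) <= params.ribbon_angular_span / 2.0
    band = (rho <= r_out) & (rho >= np.maximum(r_in, 0.0))
    mask = band & in_sector
    if not mask.any():
        raise GenerationError(
            "phantom parameters produced an empty ribbon mask "
            f"(thickness={params.ribbon_thickness}, "
            f"span={params.ribbon_angular_span})")
    return BinaryMask(mask.astype(np.uint8))


def brain_support(params: PhantomParams, instance_seed: int) -> BinaryMask:
    """Binary support of the whole (deformed) brain ellipse."""
    cy, cx, theta0, radius = _geometry(params, instance_seed)
    rho, theta = _polar(params, cy, cx)
    return BinaryMask((rho <= radius(theta)).astype(np.uint8))


def render_slice(mask: BinaryMask, params: PhantomParams,
                 instance_seed: int) -> ImageSlice:
    """Low-contrast, blurred, noisy intensity slice for a given mask."""
    if mask.pixels.shape != (params.image_size, params.image_size):
        raise ValueError(
            f"mask shape {mask.pixels.shape} incompatible with "
            f"image_size {params.image_size}")
    brain = brain_support(params, instance_seed).pixels.astype(bool)
    img = np.zeros((params.image_size, params.image_size), dtype=np.float64)
    img[brain] = params.tissue_level
    img[mask.pixels.astype(bool)] = params.tissue_level + params.contrast_gap
    if params.blur_sigma > 0:
        img = gaussian_filter(img, params.blur_sigma)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(params.seed) % (2**31), int(instance_seed), 1]))
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    return ImageSlice(np.clip(img, 0.0, 1.0),
                      provenance=f"phantom:seed={params.seed}/{instance_seed}")


def generate_dataset(params: PhantomParams, n: int, seed: int) -> PairedDataset:
    """``n`` independent (slice, mask) pairs, a pure function of inputs.

    The dataset seed replaces ``params.seed``; instance ``i`` uses
    instance seed ``i``.
    """
    if n < 1:
        raise ValueError(f"dataset size must be >= 1, got {n}")
    p = replace(params, seed=int(seed))
    pairs = []
    for i in range(n):
        msk = generate_mask(p, i)
        img = render_slice(msk, p, i)
        pairs.append((img, msk))
    return PairedDataset(pairs)


def split_dataset(ds: PairedDataset, n_train: int, n_val: int,
                  n_test: int) -> PairedDataset:
    """Tag the first ``n_train`` pairs train, then val, then test."""
    if n_train + n_val + n_test != len(ds):
        raise ValueError("split sizes must sum to dataset size")
    tags = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    return PairedDataset(list(ds.pairs), tags)
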
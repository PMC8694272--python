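"""Adversarial segmentation: U-net generator, conditional discriminator,
the fused three-term generator objective and the alternating trainer.

The generator G maps a PET slice ``x`` to a soft cortex mask ``G(x)``.
The discriminator D sees the (image, mask) pair as a two-channel input
and outputs the probability that the mask is the real annotation. The
generator minimizes

    L_G = Ld + lambda1 * Lu + lambda2 * Le

with Ld = E[-log D(x, G(x))] the non-saturating adversarial term,
Lu the smoothed soft Dice loss against the ground truth, and Le the
frozen-CAE latent distance (see :mod:`fspet.cae`). The discriminator
minimizes LD = E[-log D(x, y)] + E[-log(1 - D(x, G(x)))]. Optimization
alternates one D update and one G update per minibatch, with Adam.

Ablations are configuration states of the same loop: ``lambda2 = 0``
gives the cGAN-Unet configuration, ``adversarial = False`` plus
``lambda2 = 0`` plain U-net training (the Dice term is then the only
objective; its lambda1 scaling is immaterial under Adam).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cae import CAEModel
from .data_io import BinaryMask, PairedDataset
from .exceptions import ConfigurationError, DataError
from .nn import (Adam, Conv2d, Dense, Flatten, LeakyReLU, Sequential, UNet,
                 sigmoid)

__all__ = ["LossWeights", "GANConfig", "GeneratorModel", "DiscriminatorModel",
           "generator_forward", "dice_loss", "adversarial_g_loss",
           "generator_total_loss", "discriminator_loss", "train_fspet",
           "predict_mask"]

EPS = 1e-7          # clamp for all log/BCE arguments
DICE_SMOOTH = 1.0   # smoothing constant of the soft Dice loss


@dataclass(frozen=True)
class LossWeights:
    """Weights of the Dice (lambda1) and latent (lambda2) terms."""

    lambda1: float = 1e-2
    lambda2: float = 1e-4

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class GANConfig:
    """Trainer hyperparameters (Adam, lr 1e-4, batch 32, 30 epochs by
    default; one D step then one G step per minibatch)."""

    lr: float = 1e-4
    d_lr: float | None = None     # defaults to lr
    epochs: int = 30
    batch_size: int = 32
    weights: LossWeights = field(default_factory=LossWeights)
    adversarial: bool = True
    depth: int = 4
    base_filters: int = 8
    d_base_filters: int = 8
    batchnorm: bool = True
    seed: int = 0
    dtype: type = np.float32


class GeneratorModel:
    """U-net with a terminal sigmoid producing soft masks in [0, 1]."""

    def __init__(self, depth: int = 4, base_filters: int = 8, seed: int = 0,
                 dtype=np.float32, batchnorm: bool = True):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
        self.depth = depth
        self.base_filters = base_filters
        self.batchnorm = batchnorm
        self.net = UNet(1, depth=depth, base_filters=base_filters, rng=rng,
                        dtype=dtype, batchnorm=batchnorm)
        self.dtype = dtype

    def _check(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=self.dtype)
        if images.ndim == 2:
            images = images[None, None]
        if images.ndim != 4 or images.shape[1] != 1:
            raise DataError(f"expected (n, 1, H, W) image batch, got "
                            f"{images.shape}")
        h, w = images.shape[2:]
        div = 2 ** self.depth
        if h % div or w % div:
            pad_h = (div - h % div) % div
            pad_w = (div - w % div) % div
            raise DataError(
                f"image dims ({h}, {w}) not divisible by 2^depth={div}; "
                f"pad to ({h + pad_h}, {w + pad_w})")
        return images

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Soft masks, shape (n, 1, H, W). Deterministic when train=False."""
        logits = self.net.forward(self._check(images), train=train)
        probs = sigmoid(logits)
        if train:
            self._probs = probs
        return probs

    def backward_from_probs(self, dprobs: np.ndarray) -> None:
        p = self._probs
        self.net.backward((dprobs * p * (1.0 - p)).astype(self.dtype))

    def predict_mask(self, images: np.ndarray, threshold: float = 0.5
                     ) -> np.ndarray:
        """Binarize G(x) at ``threshold`` (ties >= go to foreground)."""
        if not 0.0 < threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {threshold}")
        return (self.forward(images, train=False) >= threshold).astype(np.uint8)

    def state(self):
        return self.net.state()


class DiscriminatorModel:
    """Conditional CNN on the 2-channel (image, mask) concatenation.

    Four stride-2 3x3 convolutions with LeakyReLU, then a dense layer to
    a single real/fake logit per pair.
    """

    def __init__(self, input_size: int, base_filters: int = 8, seed: int = 0,
                 dtype=np.float32):
        if input_size % 16:
            raise ConfigurationError("discriminator needs input divisible by 16")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
        f = base_filters
        self.input_size = input_size
        self.dtype = dtype
        self.net = Sequential([
            Conv2d(2, f, 3, stride=2, rng=rng, dtype=dtype), LeakyReLU(0.2),
            Conv2d(f, 2 * f, 3, stride=2, rng=rng, dtype=dtype), LeakyReLU(0.2),
            Conv2d(2 * f, 4 * f, 3, stride=2, rng=rng, dtype=dtype),
            LeakyReLU(0.2),
            Conv2d(4 * f, 8 * f, 3, stride=2, rng=rng, dtype=dtype),
            LeakyReLU(0.2),
            Flatten(),
            Dense(8 * f * (input_size // 16) ** 2, 1, rng=rng, dtype=dtype),
        ])

    def logits(self, images: np.ndarray, masks: np.ndarray,
               train: bool = False) -> np.ndarray:
        x = np.concatenate([np.asarray(images, dtype=self.dtype),
                            np.asarray(masks, dtype=self.dtype)], axis=1)
        return self.net.forward(x, train=train)[:, 0]

    def prob(self, images: np.ndarray, masks: np.ndarray) -> np.ndarray:
        """P(real | image, mask) in (0, 1), one value per pair."""
        return sigmoid(self.logits(images, masks, train=False))

    def state(self):
        return self.net.state()


def _pair_batch(a) -> np.ndarray:
    arr = a.pixels if hasattr(a, "pixels") else np.asarray(a)
    if arr.ndim == 2:
        arr = arr[None, None]
    return arr.astype(np.float64)


def generator_forward(model: GeneratorModel, image) -> np.ndarray:
    """Inference-mode soft mask for a single 2-D image."""
    return np.asarray(model.forward(_pair_batch(image), train=False),
                      dtype=np.float64)[0, 0]


def predict_mask(model: GeneratorModel, image, threshold: float = 0.5):
    """Binary mask of one slice at the given threshold."""
    out = model.predict_mask(_pair_batch(image), threshold=threshold)
    return BinaryMask(out[0, 0])


# ---------------------------------------------------------------------------
# losses (value level)

def dice_loss(prediction, truth, smooth: float = DICE_SMOOTH) -> float:
    """Soft Dice loss 1 - (2*sum(p*y)+s) / (sum(p)+sum(y)+s), in [0, 1].

    Batched inputs are averaged per sample.
    """
    p = _pair_batch(prediction)
    y = _pair_batch(truth)
    if p.shape != y.shape:
        raise DataError(f"shape mismatch: {p.shape} vs {y.shape}")
    ax = (1, 2, 3)
    num = 2.0 * np.sum(p * y, axis=ax) + smooth
    den = np.sum(p, axis=ax) + np.sum(y, axis=ax) + smooth
    return float(np.mean(1.0 - num / den))


def _dice_loss_grad(p: np.ndarray, y: np.ndarray, smooth: float = DICE_SMOOTH
                    ) -> np.ndarray:
    """d(mean soft Dice loss)/dp for an (n, 1, H, W) batch."""
    ax = (1, 2, 3)
    num = 2.0 * np.sum(p * y, axis=ax, keepdims=True) + smooth
    den = np.sum(p, axis=ax, keepdims=True) + np.sum(y, axis=ax,
                                                     keepdims=True) + smooth
    return -(2.0 * y * den - num) / (den ** 2) / p.shape[0]


def adversarial_g_loss(d: DiscriminatorModel, image, prediction) -> float:
    """Non-saturating generator term E[-log D(x, G(x))], clamped."""
    q = np.clip(d.prob(_pair_batch(image), _pair_batch(prediction)),
                EPS, 1.0 - EPS)
    return float(np.mean(-np.log(q)))


def discriminator_loss(d: DiscriminatorModel, image, truth, prediction) -> float:
    """E[-log D(x, y)] - E[log(1 - D(x, G(x)))], clamped; >= 0."""
    x = _pair_batch(image)
    qr = np.clip(d.prob(x, _pair_batch(truth)), EPS, 1.0 - EPS)
    qf = np.clip(d.prob(x, _pair_batch(prediction)), EPS, 1.0 - EPS)
    return float(np.mean(-np.log(qr)) + np.mean(-np.log1p(-qf)))


def generator_total_loss(d: DiscriminatorModel, cae: CAEModel, image,
                         prediction, truth,
                         weights: LossWeights = LossWeights()
                         ) -> tuple[float, dict]:
    """Fused objective Ld + lambda1*Lu + lambda2*Le with its breakdown."""
    from .cae import latent_loss
    ld = adversarial_g_loss(d, image, prediction)
    lu = dice_loss(prediction, truth)
    le = latent_loss(cae, _pair_batch(prediction), _pair_batch(truth))
    total = ld + weights.lambda1 * lu + weights.lambda2 * le
    return total, {"Ld": ld, "Lu": lu, "Le": le, "LG": total}


# ---------------------------------------------------------------------------
# training

def train_fspet(dataset: PairedDataset, cae: CAEModel | None,
                config: GANConfig | None = None
                ) -> tuple[GeneratorModel, DiscriminatorModel, list[dict]]:
    """Alternating adversarial training of the fused segmentation model.

    ``cae`` must be a trained (frozen) CAE when ``weights.lambda2 > 0``;
    it may be None otherwise. Returns the generator, the discriminator
    and a per-epoch history of the loss components (Ld, Lu, Le, LG, LD).
    """
    cfg = config or GANConfig()
    w = cfg.weights
    X = dataset.images().astype(cfg.dtype)
    Y = dataset.masks().astype(cfg.dtype)
    n, _, h, wd = X.shape
    if h != wd:
        raise ConfigurationError("training expects square slices")
    if w.lambda2 > 0:
        if cae is None:
            raise ConfigurationError("lambda2 > 0 requires a trained CAE")
        if not cae.frozen:
            raise ConfigurationError("the CAE must be frozen before "
                                     "segmentation training")
        if cae.input_size != h:
            raise ConfigurationError(
                f"CAE input size {cae.input_size} != slice size {h}")
    gen = GeneratorModel(cfg.depth, cfg.base_filters, seed=cfg.seed,
                         dtype=cfg.dtype, batchnorm=cfg.batchnorm)
    # start the mask head at the foreground-prior logit so the first
    # epochs refine shape instead of relearning the class balance
    fg = float(np.clip(Y.mean(), 1e-4, 1 - 1e-4))
    gen.net.head.b[:] = np.log(fg / (1.0 - fg))
    disc = DiscriminatorModel(h, cfg.d_base_filters, seed=cfg.seed,
                              dtype=cfg.dtype)
    gen._check(X[:1])  # validate divisibility up front
    opt_g = Adam(gen.net.params, gen.net.grads, lr=cfg.lr)
    opt_d = Adam(disc.net.params, disc.net.grads,
                 lr=cfg.d_lr if cfg.d_lr is not None else cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 41]))
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        sums = {"Ld": 0.0, "Lu": 0.0, "Le": 0.0, "LG": 0.0, "LD": 0.0}
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            m = xb.shape[0]
            ld_val = le_val = lds_val = 0.0

            if cfg.adversarial:
                # --- discriminator step (generator frozen, prediction
                # detached: it is a plain forward pass, no G gradients) ---
                p_det = gen.forward(xb, train=False)
                both = np.concatenate([
                    np.concatenate([xb, yb], axis=1),
                    np.concatenate([xb, p_det], axis=1)], axis=0)
                z = disc.net.forward(both, train=True)[:, 0]
                zr, zf = z[:m], z[m:]
                lds_val = float(np.mean(np.logaddexp(0.0, -zr)) +
                                np.mean(np.logaddexp(0.0, zf)))
                dz = np.empty_like(z)
                dz[:m] = (sigmoid(zr) - 1.0) / m
                dz[m:] = sigmoid(zf) / m
                opt_d.zero_grad()
                disc.net.backward(dz[:, None].astype(cfg.dtype))
                opt_d.step()

            # --- generator step (discriminator and CAE frozen) ---
            p = gen.forward(xb, train=True)
            dp = np.zeros_like(p, dtype=np.float64)
            if cfg.adversarial:
                zf = disc.net.forward(
                    np.concatenate([xb, p], axis=1), train=True)[:, 0]
                ld_val = float(np.mean(np.logaddexp(0.0, -zf)))
                dzf = ((sigmoid(zf) - 1.0) / m)[:, None].astype(cfg.dtype)
                dp += disc.net.backward(dzf, param_grads=False)[:, 1:2]
            lu_val = dice_loss(p, yb)
            dp += w.lambda1 * _dice_loss_grad(p.astype(np.float64),
                                             yb.astype(np.float64))
            if w.lambda2 > 0:
                ht = cae.encode_batch(yb, train=False)
                hp = cae.encode_batch(p, train=True)
                diff = (hp - ht).astype(np.float64)
                le_val = float(np.mean(diff ** 2))
                dhp = (2.0 * diff / diff.size).astype(cfg.dtype)
                dp += cae.encoder.backward(dhp, param_grads=False)
            lg_val = ld_val + w.lambda1 * lu_val + w.lambda2 * le_val
            opt_g.zero_grad()
            gen.backward_from_probs(dp)
            opt_g.step()

            for key, val in (("Ld", ld_val), ("Lu", lu_val), ("Le", le_val),
                             ("LG", lg_val), ("LD", lds_val)):
                sums[key] += val * m
        history.append({"epoch": epoch, **{k: v / n for k, v in sums.items()}})
    return gen, disc, history
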
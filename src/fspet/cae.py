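"""Convolutional auto-encoder shape prior over cortex masks.

The CAE learns a low-dimensional embedding of the anatomical shape
population: an encoder ``f`` maps a (soft or binary) mask to a latent
code ``h``, a decoder ``g`` reconstructs a [0,1] mask from ``h``.
Training minimizes mean pixelwise binary cross-entropy between a
ground-truth mask ``y`` and its reconstruction ``g(f(y))``.

Once trained the CAE is *frozen* and only its encoder is used inside
segmentation training, as the latent regularizer

    Le = E[(f(G(x)) - f(y))^2]

— the mean squared distance between the codes of the predicted soft
mask and the ground truth, averaged over batch and latent entries. Soft
predictions are encoded directly (no binarization) so the regularizer
stays differentiable. The regularizer never updates the encoder: a
frozen model back-propagates only an input gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import BinaryMask
from .exceptions import ConfigurationError, DataError, StateError
from .nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2x2, Dense, Flatten,
                 ReLU, Reshape, Sequential, sigmoid)

__all__ = ["CAEConfig", "CAEModel", "encode", "decode", "cae_loss",
           "train_cae", "latent_loss"]

EPS = 1e-7


@dataclass
class CAEConfig:
    """Hyperparameters; optimizer defaults follow the training recipe
    (Adam, lr 0.01, 30 epochs, batch 32)."""

    latent_dim: int = 64
    base_filters: int = 12
    stages: int = 4          # stride-2 conv downsamplings; mirrored up
    lr: float = 0.01
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    dtype: type = np.float32


class CAEModel:
    """Encoder f / decoder g pair over ``input_size`` square masks."""

    def __init__(self, input_size: int, config: CAEConfig | None = None):
        self.config = config or CAEConfig()
        cfg = self.config
        if input_size % (2 ** cfg.stages) != 0:
            raise ConfigurationError(
                f"input_size {input_size} not divisible by 2^{cfg.stages}")
        self.input_size = int(input_size)
        self.latent_dim = cfg.latent_dim
        self.frozen = False
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
        chans = [cfg.base_filters * (2 ** i) for i in range(cfg.stages)]
        bottom = input_size // (2 ** cfg.stages)
        enc: list = []
        cin = 1
        for c in chans:
            enc += [Conv2d(cin, c, 3, stride=2, rng=rng, dtype=cfg.dtype),
                    BatchNorm2d(c, dtype=cfg.dtype), ReLU()]
            cin = c
        enc += [Flatten(),
                Dense(cin * bottom * bottom, cfg.latent_dim, rng=rng,
                      dtype=cfg.dtype)]
        self.encoder = Sequential(enc)
        dec: list = [Dense(cfg.latent_dim, cin * bottom * bottom, rng=rng,
                           dtype=cfg.dtype),
                     ReLU(),
                     Reshape((cin, bottom, bottom))]
        for c in reversed(chans[:-1]):
            dec += [ConvTranspose2x2(cin, c, rng=rng, dtype=cfg.dtype),
                    BatchNorm2d(c, dtype=cfg.dtype), ReLU(),
                    Conv2d(c, c, 3, rng=rng, dtype=cfg.dtype),
                    BatchNorm2d(c, dtype=cfg.dtype), ReLU()]
            cin = c
        dec += [ConvTranspose2x2(cin, cin, rng=rng, dtype=cfg.dtype),
                BatchNorm2d(cin, dtype=cfg.dtype), ReLU(),
                Conv2d(cin, cin, 3, rng=rng, dtype=cfg.dtype),
                BatchNorm2d(cin, dtype=cfg.dtype), ReLU(),
                Conv2d(cin, 1, 3, rng=rng, dtype=cfg.dtype)]
        self.decoder = Sequential(dec)  # outputs logits; decode() applies sigmoid

    # -- batch-level API used by training loops ---------------------------
    def encode_batch(self, masks: np.ndarray, train: bool = False) -> np.ndarray:
        masks = np.asarray(masks, dtype=self.config.dtype)
        if masks.ndim != 4 or masks.shape[1] != 1 or \
                masks.shape[2:] != (self.input_size, self.input_size):
            raise DataError(
                f"expected (n, 1, {self.input_size}, {self.input_size}) batch, "
                f"got {masks.shape}")
        return self.encoder.forward(masks, train=train)

    def decode_batch(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=self.config.dtype)
        if codes.ndim != 2 or codes.shape[1] != self.latent_dim:
            raise DataError(f"expected (n, {self.latent_dim}) codes, "
                            f"got {codes.shape}")
        if not np.all(np.isfinite(codes)):
            raise DataError("non-finite latent code")
        return sigmoid(self.decoder.forward(codes, train=False))

    def freeze(self) -> None:
        """Pin the model: batch-norm layers switch to running statistics
        permanently and the latent regularizer becomes available."""
        for layer in self.encoder.layers + self.decoder.layers:
            if isinstance(layer, BatchNorm2d):
                layer.freeze()
        self.frozen = True

    def params_snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in self.encoder.params + self.decoder.params]


def _as_batch(mask, size: int) -> np.ndarray:
    arr = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    if arr.ndim == 2:
        arr = arr[None, None]
    if arr.shape[-2:] != (size, size):
        raise DataError(f"mask shape {arr.shape[-2:]} != model input "
                        f"({size}, {size})")
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise DataError("mask values must lie in [0, 1]")
    return arr.astype(np.float64)


def encode(model: CAEModel, mask) -> np.ndarray:
    """Latent code f(mask) of one 2-D soft or binary mask."""
    return np.asarray(model.encode_batch(_as_batch(mask, model.input_size)))[0]


def decode(model: CAEModel, code: np.ndarray) -> np.ndarray:
    """Soft mask g(code) in [0, 1] of one latent code."""
    code = np.asarray(code, dtype=np.float64)
    if code.ndim != 1 or code.size != model.latent_dim:
        raise DataError(f"code length {code.size} != latent_dim "
                        f"{model.latent_dim}")
    return np.asarray(model.decode_batch(code[None]))[0, 0].astype(np.float64)


def cae_loss(reconstruction: np.ndarray, target) -> float:
    """Mean pixelwise binary cross-entropy, probabilities clamped at 1e-7."""
    target_arr = target.pixels if isinstance(target, BinaryMask) \
        else np.asarray(target)
    rec = np.asarray(reconstruction, dtype=np.float64)
    if rec.shape != target_arr.shape:
        raise DataError(f"shape mismatch: {rec.shape} vs {target_arr.shape}")
    if not np.isin(target_arr, (0, 1)).all():
        raise DataError("cae_loss target must be binary")
    p = np.clip(rec, EPS, 1.0 - EPS)
    y = target_arr.astype(np.float64)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log1p(-p))))


def train_cae(masks, config: CAEConfig | None = None) -> tuple[CAEModel, list]:
    """Fit the auto-encoder on a population of binary masks.

    ``masks`` is a list of ``BinaryMask`` (or 2-D arrays) or an
    (n, 1, H, W) array. Returns the trained, frozen model and the
    per-epoch mean BCE training-loss curve. Gradients flow through a
    numerically fused sigmoid+BCE on decoder logits.
    """
    cfg = config or CAEConfig()
    if isinstance(masks, np.ndarray):
        batch = masks.astype(cfg.dtype)
        if batch.ndim != 4:
            raise DataError("mask array must have shape (n, 1, H, W)")
    else:
        masks = list(masks)
        if len(masks) == 0:
            raise DataError("cannot train a CAE on an empty mask set")
        arrs = [m.pixels if isinstance(m, BinaryMask) else np.asarray(m)
                for m in masks]
        batch = np.stack(arrs)[:, None].astype(cfg.dtype)
    n = batch.shape[0]
    model = CAEModel(batch.shape[-1], cfg)
    # start the output layer at the foreground-prior logit so early epochs
    # are spent on shape, not on relearning the background rate
    fg = float(np.clip(batch.mean(), 1e-4, 1 - 1e-4))
    model.decoder.layers[-1].b[:] = np.log(fg / (1.0 - fg))
    params = model.encoder.params + model.decoder.params
    grads = model.encoder.grads + model.decoder.grads
    opt = Adam(params, grads, lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            yb = batch[order[start:start + cfg.batch_size]]
            m = yb.shape[0]
            codes = model.encoder.forward(yb, train=True)
            logits = model.decoder.forward(codes, train=True)
            # stable BCE on logits: softplus(z) - z*y
            loss = float(np.mean(np.logaddexp(0.0, logits) - logits * yb))
            dlogits = (sigmoid(logits) - yb) / logits.size
            opt.zero_grad()
            dcode = model.decoder.backward(dlogits.astype(cfg.dtype))
            model.encoder.backward(dcode)
            opt.step()
            losses.append((loss, m))
        history.append(sum(l * m for l, m in losses) / n)
    model.freeze()
    return model, history


def latent_loss(model: CAEModel, prediction, truth) -> float:
    """Shape-prior regularizer: mean squared latent distance
    ``mean((f(prediction) - f(truth))^2)`` over batch and latent entries.

    Requires a frozen model — the regularizer must never update f.
    """
    if not model.frozen:
        raise StateError("latent_loss requires a frozen (trained) CAE")
    p = _as_batch(prediction, model.input_size)
    t = _as_batch(truth, model.input_size)
    if p.shape != t.shape:
        raise DataError(f"shape mismatch: {p.shape} vs {t.shape}")
    hp = np.asarray(model.encode_batch(p), dtype=np.float64)
    ht = np.asarray(model.encode_batch(t), dtype=np.float64)
    return float(np.mean((hp - ht) ** 2))
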
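"""Network containers: a plain Sequential and a U-net with skip connections."""

from __future__ import annotations

import numpy as np

from .layers import (BatchNorm2d, Conv2d, ConvTranspose2x2, Layer, MaxPool2x2,
                     ReLU)

__all__ = ["Sequential", "UNet"]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout, param_grads=True):
        for l in reversed(self.layers):
            dout = l.backward(dout, param_grads=param_grads)
        return dout

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state, strict=True):
            p[...] = s


def _conv_block(cin, cout, rng, dtype, batchnorm):
    block = [Conv2d(cin, cout, 3, rng=rng, dtype=dtype)]
    if batchnorm:
        block.append(BatchNorm2d(cout, dtype=dtype))
    block.append(ReLU())
    block.append(Conv2d(cout, cout, 3, rng=rng, dtype=dtype))
    if batchnorm:
        block.append(BatchNorm2d(cout, dtype=dtype))
    block.append(ReLU())
    return block


class UNet:
    """Encoder-decoder with skip connections.

    Contracting path: ``depth`` levels of two 3x3 conv + ReLU followed by
    2x2 max pooling, channel count doubling from ``base_filters``.
    Expansive path: 2x2 transposed convolutions, concatenation with the
    matching skip tensor, then two 3x3 conv + ReLU. A final 1x1
    convolution maps to a single-channel logit map; the caller applies a
    sigmoid (kept outside so losses can work on logits when convenient).
    Input height/width must be divisible by ``2**depth``.
    """

    def __init__(self, in_channels: int = 1, depth: int = 4, base_filters: int = 8,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 batchnorm: bool = True):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.batchnorm = batchnorm
        self.enc_blocks: list[Sequential] = []
        self.pools: list[MaxPool2x2] = []
        ch = in_channels
        for d in range(depth):
            f = base_filters * (2 ** d)
            self.enc_blocks.append(Sequential(_conv_block(ch, f, rng, dtype, batchnorm)))
            self.pools.append(MaxPool2x2())
            ch = f
        self.bottleneck = Sequential(_conv_block(ch, ch * 2, rng, dtype, batchnorm))
        ch *= 2
        self.ups: list[ConvTranspose2x2] = []
        self.dec_blocks: list[Sequential] = []
        for d in reversed(range(depth)):
            f = base_filters * (2 ** d)
            self.ups.append(ConvTranspose2x2(ch, f, rng=rng, dtype=dtype))
            self.dec_blocks.append(Sequential(_conv_block(2 * f, f, rng, dtype, batchnorm)))
            ch = f
        self.head = Conv2d(ch, 1, k=1, pad=0, rng=rng, dtype=dtype)

    def _modules(self):
        mods: list = []
        mods.extend(self.enc_blocks)
        mods.append(self.bottleneck)
        mods.extend(self.ups)
        mods.extend(self.dec_blocks)
        mods.append(self.head)
        return mods

    @property
    def params(self):
        return [p for m in self._modules() for p in m.params]

    @property
    def grads(self):
        return [g for m in self._modules() for g in m.grads]

    def zero_grad(self):
        for m in self._modules():
            if isinstance(m, Sequential):
                m.zero_grad()
            else:
                m.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Return single-channel logits of the same spatial size as ``x``."""
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = blk.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train=train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, dout: np.ndarray, param_grads: bool = True) -> np.ndarray:
        dout = self.head.backward(dout, param_grads=param_grads)
        dskips = []
        for up, blk, ns in zip(reversed(self.ups), reversed(self.dec_blocks),
                               reversed(self._skip_channels)):
            d = blk.backward(dout, param_grads=param_grads)
            dskips.append(d[:, :ns])
            dout = up.backward(d[:, ns:], param_grads=param_grads)
        dout = self.bottleneck.backward(dout, param_grads=param_grads)
        for blk, pool, dskip in zip(reversed(self.enc_blocks), reversed(self.pools),
                                    reversed(dskips)):
            d = pool.backward(dout, param_grads=param_grads)
            dout = blk.backward(d + dskip, param_grads=param_grads)
        return dout

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state, strict=True):
            p[...] = s
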
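"""Minimal NumPy layer library with explicit forward/backward passes.

All layers operate on NCHW float arrays (or NxD for dense layers). Each
layer caches what its backward pass needs during ``forward`` and exposes
``params`` / ``grads`` lists that an optimizer consumes. ``backward``
always returns the gradient with respect to the layer input; parameter
gradients are accumulated into ``grads`` unless ``param_grads=False``
(used when a frozen network is back-propagated through only to obtain an
input gradient, e.g. the shape-prior encoder).

The library is deliberately small: 3x3 (and 1x1) convolutions with
arbitrary stride, 2x2 stride-2 transposed convolutions, 2x2 max pooling,
dense layers and the usual pointwise activations - exactly what the U-net
generator, the conditional discriminator and the convolutional
auto-encoder require.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ConvTranspose2x2",
    "MaxPool2x2",
    "Dense",
    "BatchNorm2d",
    "Flatten",
    "Reshape",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
]


class Layer:
    """Base class: stateless layers only need ``forward``/``backward``."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray, param_grads: bool = True) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Layer):
    """k x k convolution, stride ``s``, symmetric zero padding ``pad``.

    Implemented as k*k shifted tensor contractions rather than one large
    im2col matrix: the same FLOPs without materialising an N*OH*OW x C*k*k
    buffer, which keeps peak memory proportional to the activations.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if pad is None:
            pad = k // 2
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        self.W = he_init(rng, (cout, cin, k, k), cin * k * k, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train=True):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, _, hp, wp = xp.shape
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        out = np.empty((n, self.cout, oh, ow), dtype=x.dtype)
        out[:] = self.b[None, :, None, None]
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di:di + s * (oh - 1) + 1:s, dj:dj + s * (ow - 1) + 1:s]
                out += np.einsum("fc,nchw->nfhw", self.W[:, :, di, dj], xs,
                                 optimize=True)
        if train:
            self._xp = xp
            self._xshape = x.shape
        return out

    def backward(self, dout, param_grads=True):
        k, s, p = self.k, self.stride, self.pad
        xp = self._xp
        n, _, hp, wp = xp.shape
        oh, ow = dout.shape[2], dout.shape[3]
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                sl_h = slice(di, di + s * (oh - 1) + 1, s)
                sl_w = slice(dj, dj + s * (ow - 1) + 1, s)
                if param_grads:
                    xs = xp[:, :, sl_h, sl_w]
                    self.dW[:, :, di, dj] += np.einsum(
                        "nfhw,nchw->fc", dout, xs, optimize=True)
                dxp[:, :, sl_h, sl_w] += np.einsum(
                    "nfhw,fc->nchw", dout, self.W[:, :, di, dj], optimize=True)
        if param_grads:
            self.db += dout.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (non-overlapping up-conv)."""

    def __init__(self, cin: int, cout: int, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.W = he_init(rng, (cin, cout, 2, 2), cin, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        cout = self.W.shape[1]
        t = np.einsum("nchw,cfij->nfhiwj", x, self.W, optimize=True)
        out = t.reshape(n, cout, 2 * h, 2 * w)
        out += self.b[None, :, None, None]
        if train:
            self._x = x
        return out

    def backward(self, dout, param_grads=True):
        x = self._x
        n, c, h, w = x.shape
        cout = self.W.shape[1]
        dt = dout.reshape(n, cout, h, 2, w, 2)
        if param_grads:
            self.dW += np.einsum("nchw,nfhiwj->cfij", x, dt, optimize=True)
            self.db += dout.sum(axis=(0, 2, 3))
        return np.einsum("nfhiwj,cfij->nchw", dt, self.W, optimize=True)


class MaxPool2x2(Layer):
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (n, c, h, w)
        return out

    def backward(self, dout, param_grads=True):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.W = he_init(rng, (din, dout), din, dtype)
        self.b = np.zeros(dout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout, param_grads=True):
        if param_grads:
            self.dW += self._x.T @ dout
            self.db += dout.sum(axis=0)
        return dout @ self.W.T


class Flatten(Layer):
    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, param_grads=True):
        return dout.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple):
        self.shape = shape  # per-sample shape, e.g. (C, H, W)

    def forward(self, x, train=True):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout, param_grads=True):
        return dout.reshape(dout.shape[0], -1)


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout, param_grads=True):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.where(x > 0, x, self.slope * x)

    def backward(self, dout, param_grads=True):
        return np.where(self._mask, dout, self.slope * dout)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        out = sigmoid(x)
        if train:
            self._out = out
        return out

    def backward(self, dout, param_grads=True):
        return dout * self._out * (1.0 - self._out)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learned scale/shift.

    ``train=True`` normalizes by batch statistics and updates running
    moments; ``train=False`` (or a frozen layer) uses the running
    moments, making the layer a fixed affine map. ``freeze()`` pins that
    behaviour permanently — used when a trained network (the CAE
    encoder) later serves as a frozen regularizer that must not change
    in any way while being back-propagated through.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self.frozen = False

    def freeze(self) -> None:
        self.frozen = True

    def forward(self, x, train=True):
        c = x.shape[1]
        if train and not self.frozen:
            mu = x.mean(axis=(0, 2, 3), dtype=np.float64)
            var = x.var(axis=(0, 2, 3), dtype=np.float64)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
            xhat = xhat.astype(x.dtype)
            self._cache = ("batch", xhat, inv)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = ((x - self.running_mean.reshape(1, c, 1, 1))
                    * inv.reshape(1, c, 1, 1)).astype(x.dtype)
            if train:
                self._cache = ("running", xhat, inv)
        return self.gamma.reshape(1, c, 1, 1) * xhat \
            + self.beta.reshape(1, c, 1, 1)

    def backward(self, dout, param_grads=True):
        mode, xhat, inv = self._cache
        c = dout.shape[1]
        if param_grads:
            self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
            self.dbeta += dout.sum(axis=(0, 2, 3))
        g = self.gamma.reshape(1, c, 1, 1)
        if mode == "running":
            return dout * g * inv.reshape(1, c, 1, 1).astype(dout.dtype)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - s1 / m - xhat * s2 / m) * inv.reshape(1, c, 1, 1)
        return dx.astype(dout.dtype)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
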
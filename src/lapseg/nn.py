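"""Minimal NumPy neural-network core with hand-derived backpropagation.

Provides exactly the layers needed by the encoder-decoder segmentation
network: same-padded 2-D convolution, batch normalization, 2x2 max pooling,
2x2 stride-2 transposed convolution, elementwise activations, and channel
concatenation.  Tensors are float32 NCHW.  Every layer caches what its
backward pass needs during ``forward`` and accumulates parameter gradients
in ``.grads`` during ``backward``; gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .activations import activation_fn, activation_grad

__all__ = [
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "Activation",
    "MaxPool2d",
    "ConvTranspose2d",
    "Sequential",
]


def _patches(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding k-by-k patch view of a (N, C, H, W) array, valid positions."""
    n, c, h, w = x.shape
    sn, sc, sh, sw = x.strides
    return as_strided(
        x,
        shape=(n, c, h - k + 1, w - k + 1, k, k),
        strides=(sn, sc, sh, sw, sh, sw),
        writeable=False,
    )


class Layer:
    """Base class: a differentiable module with named parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    """Same-padded convolution (cross-correlation) with odd kernel size."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.k, self.pad = k, k // 2
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init
        self.params = {
            "W": rng.normal(0.0, scale, (c_out, c_in, k, k)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        pat = _patches(xp, self.k)
        w = self.params["W"]
        # (N,H,W,O) <- sum over C,k,k
        y = np.tensordot(pat, w, axes=([1, 4, 5], [1, 2, 3]))
        y += self.params["b"]
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.pad
        pat = _patches(self._xp, k)
        # dW[o,c,i,j] = sum_{n,h,w} x_pad[n,c,h+i,w+j] dy[n,o,h,w]
        dw = np.tensordot(dy, pat, axes=([0, 2, 3], [0, 2, 3]))
        self.grads["W"] += dw
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        # full correlation of dy with tap-flipped kernels
        dyp = np.pad(dy, ((0, 0), (0, 0), (k - 1 - p, k - 1 - p), (k - 1 - p, k - 1 - p)))
        dpat = _patches(dyp, k)
        wf = self.params["W"][:, :, ::-1, ::-1]
        dx = np.tensordot(dpat, wf, axes=([1, 4, 5], [0, 2, 3]))
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {
            "gamma": np.ones(c, dtype=np.float32),
            "beta": np.zeros(c, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.params["gamma"][:, None, None]
        b = self.params["beta"][:, None, None]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * ivar[:, None, None]
        if train:
            self._cache = (xhat, ivar)
        return (g * xhat + b).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][:, None, None]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2, 3))[:, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        dx = (dxhat - s1 / m - xhat * s2 / m) * ivar[:, None, None]
        return dx.astype(np.float32)


class Activation(Layer):
    """Elementwise ReLU / GELU / Swish."""

    def __init__(self, kind: str):
        super().__init__()
        self.kind = kind

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return activation_fn(self.kind)(x).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy * activation_grad(self.kind)(self._x)).astype(np.float32)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; ties resolve to the first (row-major) element."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xv = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xv = xv.reshape(n, c, h // 2, w // 2, 4)
        idx = xv.argmax(axis=-1)
        if train:
            self._idx, self._shape = idx, x.shape
        return np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(out, self._idx[..., None], dy[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(out.reshape(n, c, h, w))


class ConvTranspose2d(Layer):
    """2x2, stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / c_in)
        self.params = {
            "W": rng.normal(0.0, scale, (c_in, c_out, 2, 2)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        n, c, h, w = x.shape
        y = np.einsum("nchw,coab->nohawb", x, self.params["W"], optimize=True)
        o = self.params["W"].shape[1]
        y = y.reshape(n, o, 2 * h, 2 * w)
        y += self.params["b"][:, None, None]
        return np.ascontiguousarray(y.astype(np.float32))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, o, h2, w2 = dy.shape
        dyv = dy.reshape(n, o, h2 // 2, 2, w2 // 2, 2)
        x = self._x
        self.grads["W"] += np.einsum("nchw,nohawb->coab", x, dyv, optimize=True)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("nohawb,coab->nchw", dyv, self.params["W"], optimize=True)
        return np.ascontiguousarray(dx.astype(np.float32))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for lay in self.layers:
            lay.zero_grad()
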
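"""Minimal NumPy neural-network layers with analytic backpropagation.

These building blocks exist to support the densely connected convolutional
feature extractor in :mod:`p2c.backbone`.  Each layer is a small stateful
module: ``forward(x, training)`` caches what backward needs, ``backward(dout)``
returns the gradient w.r.t. the input and fills ``grads`` for every entry in
``params``.  Arrays are NCHW float32 for convolutional layers.

Gradients are hand-derived and verified against central differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d", "BatchNorm2d", "ReLU", "AvgPool2d", "GlobalAvgPool",
    "Linear", "Dropout", "softmax_cross_entropy",
]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (n, c, ho, wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols, x_shape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Module:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}


class Conv2d(Module):
    """2D convolution (no bias; always followed by batch norm here)."""

    def __init__(self, in_c: int, out_c: int, ksize: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_c, self.out_c = in_c, out_c
        self.ksize, self.stride, self.pad = ksize, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_c * ksize * ksize
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.params["W"] = (rng.standard_normal((out_c, in_c, ksize, ksize)) * scale).astype(np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.ksize, self.ksize, self.stride, self.pad)
        wmat = self.params["W"].reshape(self.out_c, -1)
        out = cols @ wmat.T
        self._cache = (cols, x.shape, ho, wo)
        n = x.shape[0]
        return out.reshape(n, ho, wo, self.out_c).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        n = x_shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_c)
        self.grads["W"] = (dmat.T @ cols).reshape(self.params["W"].shape)
        dcols = dmat @ self.params["W"].reshape(self.out_c, -1)
        return _col2im(dcols, x_shape, self.ksize, self.ksize, self.stride, self.pad, ho, wo)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training)
        return g * xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, training = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not training:
            return dout * g * inv_std[None, :, None, None]
        n, _, h, w = dout.shape
        m = n * h * w
        dxhat = dout * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv_std[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class ReLU(Module):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool2d(Module):
    """2x2 average pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"AvgPool2d requires even spatial dims, got {h}x{w}")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Linear(Module):
    def __init__(self, in_d: int, out_d: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_d)
        self.params["W"] = (rng.standard_normal((out_d, in_d)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(out_d, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class Dropout(Module):
    """Inverted dropout; identity when evaluating or when p == 0."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs an RNG"
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits.

    ``labels`` are integer class indices.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
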
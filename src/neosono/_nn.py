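"""Minimal NumPy neural-network engine for the composite classifier.

Implements exactly the pieces the architecture needs — same-padded 2-D
convolution (im2col + GEMM), spatial batch normalisation, ReLU, 2 x 2
stride-2 max pooling with floor division, a dense head, softmax
cross-entropy, and RMSProp — in float32, single-threaded deterministic
given a seeded ``numpy.random.Generator``.

Activations are ``(N, H, W, C)`` channels-last.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Network",
    "RMSProp",
    "softmax",
    "softmax_cross_entropy",
]

_F32 = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-shift stabilisation."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.sum(onehot * np.log(p + eps)) / n)
    grad = ((p - onehot) / n).astype(_F32)
    return loss, grad


class Layer:
    """Base layer: optional parameters, forward/backward passes."""

    def params_grads(self):
        return []

    def forward(self, x, train: bool):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded k x k convolution, stride 1, channels-last."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        fan_in = kernel * kernel * c_in
        # He initialisation: ReLU follows every convolution here.
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._x_shape = None

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train: bool):
        k = self.kernel
        pad = k // 2
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (n,h,w,c,k,k)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
        cols = np.ascontiguousarray(cols, dtype=_F32)
        out = cols @ self.W + self.b
        if train:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout):
        k = self.kernel
        pad = k // 2
        n, h, w, _ = self._x_shape
        dflat = dout.reshape(n * h * w, self.c_out).astype(_F32)
        self.dW[...] = self._cols.T @ dflat
        self.db[...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(n, h, w, k, k, self.c_in)
        dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, self.c_in), dtype=_F32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, pad : pad + h, pad : pad + w, :]


class BatchNorm2D(Layer):
    """Per-channel batch normalisation over the (N, H, W) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache = None

    def params_grads(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, train: bool):
        if train:
            mean = x.mean(axis=(0, 1, 2), dtype=np.float64)
            var = x.var(axis=(0, 1, 2), dtype=np.float64)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        xhat = (x - mean.astype(_F32)) * inv_std
        out = self.gamma * xhat + self.beta
        if train:
            self._cache = (xhat, inv_std)
        return out

    def backward(self, dout):
        xhat, inv_std = self._cache
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.dgamma[...] = np.sum(dout * xhat, axis=(0, 1, 2))
        self.dbeta[...] = np.sum(dout, axis=(0, 1, 2))
        dx = (self.gamma * inv_std / m) * (
            m * dout
            - self.dbeta
            - xhat * self.dgamma
        )
        self._cache = None
        return dx.astype(_F32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train: bool):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2D(Layer):
    """2 x 2 stride-2 max pooling; odd trailing rows/cols are dropped (floor)."""

    def __init__(self, size: int = 2, stride: int = 2):
        if size != stride:
            raise ValueError("only size == stride pooling is supported")
        self.size = size
        self._cache = None

    def forward(self, x, train: bool):
        s = self.size
        n, h, w, c = x.shape
        h2, w2 = h // s, w // s
        xc = x[:, : h2 * s, : w2 * s, :]
        win = xc.reshape(n, h2, s, w2, s, c).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(n, h2, w2, s * s, c)
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._cache = (x.shape, idx)
        return out

    def backward(self, dout):
        s = self.size
        (n, h, w, c), idx = self._cache
        h2, w2 = h // s, w // s
        dwin = np.zeros((n, h2, w2, s * s, c), dtype=_F32)
        np.put_along_axis(dwin, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dxc = dwin.reshape(n, h2, w2, s, s, c).transpose(0, 1, 3, 2, 4, 5)
        dxc = dxc.reshape(n, h2 * s, w2 * s, c)
        dx = np.zeros((n, h, w, c), dtype=_F32)
        dx[:, : h2 * s, : w2 * s, :] = dxc
        self._cache = None
        return dx


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train: bool):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train: bool):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(x, dtype=_F32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params_grads()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params_grads()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params_grads(), weights, strict=True):
            p[...] = w


class RMSProp:
    """RMSProp: per-weight step size scaled by a decaying mean square gradient.

    ``c <- decay * c + (1 - decay) * g^2``;
    ``w <- w - lr * g / (sqrt(c) + eps)``. With ``lr = 0`` the weights are
    untouched regardless of the gradients.
    """

    def __init__(self, params_grads, lr: float = 1e-3, decay: float = 0.9,
                 eps: float = 1e-8):
        self.params_grads = params_grads
        self.lr = lr
        self.decay = decay
        self.eps = eps
        self.caches = [np.zeros_like(p) for p, _ in params_grads]

    def step(self) -> None:
        for (p, g), c in zip(self.params_grads, self.caches):
            c *= self.decay
            c += (1.0 - self.decay) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)
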
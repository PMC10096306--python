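"""Minimal NumPy neural-network layers with manual backpropagation.

Just enough machinery for the two-branch affinity regressor: dense,
embedding, 1-D convolution (valid padding, stride 1), depthwise-separable
1-D convolution, global max-pooling, inverted dropout, and Adam.  Layers
store parameters and gradients in name-keyed dicts; ``forward`` caches
whatever ``backward`` needs.  Everything is deterministic given the
``numpy.random.Generator`` used for initialization and dropout.

Time-series tensors are channels-last: (batch, length, channels).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def relu(x):
    return np.maximum(x, 0.0)


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter store plus forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, activation="relu"):
        super().__init__()
        self.activation = activation
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Embedding(Layer):
    """Integer codes (B, L) -> dense vectors (B, L, D); code 0 is padding."""

    def __init__(self, n_codes, dim, rng):
        super().__init__()
        self.params["E"] = rng.normal(0.0, 0.05, size=(n_codes, dim))
        self.params["E"][0] = 0.0  # padding embeds to zero initially

    def forward(self, x, train=False):
        self._x = x
        return self.params["E"][x]

    def backward(self, dy):
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, self._x.ravel(), dy.reshape(-1, dy.shape[-1]))
        self.grads["E"] = dE
        return None  # integer inputs: no upstream gradient


class Conv1D(Layer):
    """Standard 1-D convolution, valid padding, stride 1, channels-last."""

    def __init__(self, c_in, c_out, kernel, rng, activation="relu"):
        super().__init__()
        self.kernel = kernel
        self.activation = activation
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.params["W"] = _glorot(rng, (kernel, c_in, c_out), fan_in, fan_out)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train=False):
        k = self.kernel
        self._windows = sliding_window_view(x, k, axis=1)  # (B, Lout, Cin, k)
        z = np.einsum("btcj,jco->bto", self._windows, self.params["W"]) + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        k = self.kernel
        self.grads["W"] = np.einsum("btcj,bto->jco", self._windows, dy)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dyp = np.pad(dy, ((0, 0), (k - 1, k - 1), (0, 0)))
        dwin = sliding_window_view(dyp, k, axis=1)  # (B, L, Cout, k)
        w_flip = self.params["W"][::-1]  # (k, Cin, Cout) reversed in tap order
        return np.einsum("btom,mco->btc", dwin, w_flip)


class SeparableConv1D(Layer):
    """Depthwise k-tap filter per channel, then pointwise channel mixing.

    Parameter count k*Cin + Cin*Cout (+ biases), versus k*Cin*Cout for a
    standard convolution of the same shape -- the economy that motivates
    using it as the final drug-branch layer.
    """

    def __init__(self, c_in, c_out, kernel, rng, activation="relu", bias=True):
        super().__init__()
        self.kernel = kernel
        self.activation = activation
        self.bias = bias
        self.params["Wd"] = _glorot(rng, (kernel, c_in), kernel, kernel)
        self.params["Wp"] = _glorot(rng, (c_in, c_out), c_in, c_out)
        if bias:
            self.params["bd"] = np.zeros(c_in)
            self.params["bp"] = np.zeros(c_out)

    def forward(self, x, train=False):
        k = self.kernel
        self._windows = sliding_window_view(x, k, axis=1)  # (B, Lout, Cin, k)
        z = np.einsum("btcj,jc->btc", self._windows, self.params["Wd"])
        if self.bias:
            z = z + self.params["bd"]
        self._z = z
        y = z @ self.params["Wp"]
        if self.bias:
            y = y + self.params["bp"]
        if self.activation == "relu":
            self._mask = y > 0
            return np.where(self._mask, y, 0.0)
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        k = self.kernel
        self.grads["Wp"] = np.einsum("btc,bto->co", self._z, dy)
        if self.bias:
            self.grads["bp"] = dy.sum(axis=(0, 1))
        dz = dy @ self.params["Wp"].T
        self.grads["Wd"] = np.einsum("btcj,btc->jc", self._windows, dz)
        if self.bias:
            self.grads["bd"] = dz.sum(axis=(0, 1))
        dzp = np.pad(dz, ((0, 0), (k - 1, k - 1), (0, 0)))
        dwin = sliding_window_view(dzp, k, axis=1)  # (B, L, Cin, k)
        wd_flip = self.params["Wd"][::-1]
        return np.einsum("btcm,mc->btc", dwin, wd_flip)


class GlobalMaxPool(Layer):
    """(B, L, C) -> (B, C), max over the length axis."""

    def forward(self, x, train=False):
        self._shape = x.shape
        self._arg = x.argmax(axis=1)  # (B, C)
        return x.max(axis=1)

    def backward(self, dy):
        B, L, C = self._shape
        dx = np.zeros(self._shape)
        b_idx = np.arange(B)[:, None]
        c_idx = np.arange(C)[None, :]
        dx[b_idx, self._arg, c_idx] = dy
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** self.t)
                vhat = v[k] / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def checksum(layers) -> float:
    """Order-stable scalar fingerprint of all parameters."""
    total = 0.0
    for l in layers:
        for k in sorted(l.params):
            total += float(np.sum(np.abs(l.params[k])))
    return total
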
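"""Minimal 1D convolutional network engine in NumPy.

Implements exactly the layer set needed by the weak-effort classifier:
1D convolution ("same" padding, im2col matmul), ReLU, max pooling,
flatten, dense, inverted dropout, and a class-weighted binary
cross-entropy on logits, trained with Adam. All layers carry analytic
backward passes; the test suite verifies them against central-difference
gradients.

Arrays are (N, C, L) for convolutional layers and (N, D) after Flatten.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "ReLU",
    "MaxPool1d",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "weighted_bce_with_logits",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> List[np.ndarray]:
        return []

    @property
    def grads(self) -> List[np.ndarray]:
        return []

    def describe(self) -> Dict:
        return {"layer": type(self).__name__}


class Conv1d(Layer):
    """1D convolution with 'same' zero padding, stride 1."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        scale = np.sqrt(2.0 / (in_ch * kernel))  # He initialization
        self.w = (rng.standard_normal((out_ch, in_ch, kernel)) * scale).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._pl = (kernel - 1) // 2
        self._pr = kernel // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, l = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self._pl, self._pr)))
        cols = sliding_window_view(xp, self.kernel, axis=2)  # (N, C, L, K)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n * l, c * self.kernel
        )
        self._cols, self._shape = cols, (n, c, l)
        wmat = self.w.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b
        return y.reshape(n, l, self.out_ch).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, l = self._shape
        k = self.kernel
        dyt = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(n * l, self.out_ch)
        wmat = self.w.reshape(self.out_ch, -1)
        self.dw[...] = (dyt.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dyt.sum(axis=0)
        dcols = (dyt @ wmat).reshape(n, l, c, k).transpose(0, 2, 1, 3)  # (N,C,L,K)
        dxp = np.zeros((n, c, l + k - 1), dtype=grad.dtype)
        for kk in range(k):
            dxp[:, :, kk : kk + l] += dcols[:, :, :, kk]
        return dxp[:, :, self._pl : self._pl + l]

    @property
    def params(self) -> List[np.ndarray]:
        return [self.w, self.b]

    @property
    def grads(self) -> List[np.ndarray]:
        return [self.dw, self.db]

    def describe(self) -> Dict:
        return {
            "layer": "Conv1d",
            "filters": self.out_ch,
            "kernel": self.kernel,
            "in_channels": self.in_ch,
            "padding": "same",
        }


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    """Max pooling with non-overlapping windows; trailing remainder dropped."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, l = x.shape
        lo = l // self.size
        xv = x[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        self._arg = xv.argmax(axis=3)
        self._shape = (n, c, l)
        return xv.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, l = self._shape
        lo = grad.shape[2]
        dxv = np.zeros((n, c, lo, self.size), dtype=grad.dtype)
        np.put_along_axis(dxv, self._arg[..., None], grad[..., None], axis=3)
        dx = np.zeros((n, c, l), dtype=grad.dtype)
        dx[:, :, : lo * self.size] = dxv.reshape(n, c, lo * self.size)
        return dx

    def describe(self) -> Dict:
        return {"layer": "MaxPool1d", "size": self.size}


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.in_dim, self.out_dim = in_dim, out_dim
        scale = np.sqrt(2.0 / in_dim)
        self.w = (rng.standard_normal((in_dim, out_dim)) * scale).astype(dtype)
        self.b = np.zeros(out_dim, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    @property
    def params(self) -> List[np.ndarray]:
        return [self.w, self.b]

    @property
    def grads(self) -> List[np.ndarray]:
        return [self.dw, self.db]

    def describe(self) -> Dict:
        return {"layer": "Dense", "units": self.out_dim, "in_dim": self.in_dim}


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask

    def describe(self) -> Dict:
        return {"layer": "Dropout", "p": self.p}


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def describe(self) -> List[Dict]:
        return [layer.describe() for layer in self.layers]

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


def weighted_bce_with_logits(
    logits: np.ndarray, y: np.ndarray, weights: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy on logits and its gradient.

    loss_i = w_i * (softplus(z_i) - y_i * z_i); numerically stable for
    large |z|. Returns (mean loss, d loss / d logits).
    """
    z = logits.astype(np.float64)
    softplus = np.logaddexp(0.0, z)
    loss = float(np.mean(weights * (softplus - y * z)))
    grad = weights * (sigmoid(z) - y) / z.size
    return loss, grad.astype(logits.dtype)


class Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g, dtype=np.float64)
            p -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(p.dtype)
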
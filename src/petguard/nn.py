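"""Minimal NumPy neural-network engine used by the demographic predictor.

Implements exactly the pieces the 64 x 64 MIP classifier needs — 3 x 3
'same' convolution, 2 x 2 max pooling, channel-wise local response
normalization, ReLU, dropout, dense layers, softmax / linear heads, Adam —
with hand-derived backward passes.  Everything is float32 and deterministic
given a seed; there is no GPU path.

Convolutions run as one SGEMM per layer over a patch matrix assembled with
nine slice copies, which is the fastest pure-NumPy formulation at these
sizes on a single CPU core.
"""

from __future__ import annotations

import copy

import numpy as np

from .errors import ConfigurationError, EmptyInputError

__all__ = [
    "softmax",
    "Conv3x3",
    "ReLU",
    "MaxPool2",
    "LRN",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax_cross_entropy",
    "mse_loss",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Probability vector F(x_i) = exp(x_i) / sum_j exp(x_j).

    Stabilized by max subtraction, hence invariant under a common additive
    shift of the logits.  Works on a single vector or a batch (last axis).
    """
    x = np.asarray(logits, dtype=np.float64)
    if x.size == 0:
        raise EmptyInputError("softmax of an empty logit vector")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("softmax requires finite logits")
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Layer:
    """Base layer: ``params`` yields (weight, gradient) pairs."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3x3(Layer):
    """3 x 3 convolution, stride 1, zero ('same') padding, NHWC layout."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * cin))  # He initialization
        self.W = (rng.standard_normal((9 * cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.cin, self.cout = cin, cout

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _col(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        col = np.empty((B, H, W, 9 * C), dtype=np.float32)
        k = 0
        for dy in range(3):
            for dx in range(3):
                col[..., k * C : (k + 1) * C] = xp[:, dy : dy + H, dx : dx + W, :]
                k += 1
        return col

    def forward(self, x, train=False):
        self._shape = x.shape
        self._colmat = self._col(x)
        B, H, W, C = x.shape
        y = self._colmat.reshape(-1, 9 * C) @ self.W
        return y.reshape(B, H, W, self.cout) + self.b

    def backward(self, dy):
        B, H, W, C = self._shape
        dyf = dy.reshape(-1, self.cout).astype(np.float32)
        colf = self._colmat.reshape(-1, 9 * C)
        self.dW[...] = colf.T @ dyf
        self.db[...] = dyf.sum(axis=0)
        dcol = (dyf @ self.W.T).reshape(B, H, W, 9 * C)
        dxp = np.zeros((B, H + 2, W + 2, C), dtype=np.float32)
        k = 0
        for ddy in range(3):
            for ddx in range(3):
                dxp[:, ddy : ddy + H, ddx : ddx + W, :] += dcol[..., k * C : (k + 1) * C]
                k += 1
        self._colmat = None
        return dxp[:, 1 : 1 + H, 1 : 1 + W, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2 x 2 max pooling, stride 2; each stage quarters the spatial element count."""

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ConfigurationError("MaxPool2 requires even spatial dims")
        self._shape = x.shape
        xr = (
            x.reshape(B, H // 2, 2, W // 2, 2, C)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(B, H // 2, W // 2, C, 4)
        )
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dy):
        B, H, W, C = self._shape
        flat = np.zeros((B, H // 2, W // 2, C, 4), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None].astype(np.float32), axis=-1)
        dx = (
            flat.reshape(B, H // 2, W // 2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(B, H, W, C)
        )
        return dx


class LRN(Layer):
    """Local response normalization across channels.

    y_c = x_c * (bias + alpha * sum_{|j - c| <= radius} x_j^2) ** (-beta)
    """

    def __init__(self, radius: int = 2, alpha: float = 1e-4, beta: float = 0.75, bias: float = 1.0):
        self.radius, self.alpha, self.beta, self.bias = radius, alpha, beta, bias

    def _window_sum(self, u: np.ndarray) -> np.ndarray:
        C = u.shape[-1]
        cs = np.concatenate(
            [np.zeros(u.shape[:-1] + (1,), dtype=u.dtype), np.cumsum(u, axis=-1)], axis=-1
        )
        hi = np.minimum(np.arange(C) + self.radius + 1, C)
        lo = np.maximum(np.arange(C) - self.radius, 0)
        return cs[..., hi] - cs[..., lo]

    def forward(self, x, train=False):
        self._x = x
        self._S = self._window_sum(x.astype(np.float32) ** 2)
        self._d = (self.bias + self.alpha * self._S) ** (-self.beta)
        return (x * self._d).astype(np.float32)

    def backward(self, dy):
        x, S, d = self._x, self._S, self._d
        u = dy * x * (self.bias + self.alpha * S) ** (-self.beta - 1.0)
        T = self._window_sum(u.astype(np.float32))
        return (dy * d - 2.0 * self.alpha * self.beta * x * T).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / nin)
        self.W = (rng.standard_normal((nin, nout)) * scale).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        dy = dy.astype(np.float32)
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ConfigurationError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray, stop_after: int = 0) -> np.ndarray:
        """Backpropagate ``dy`` from the output; returns the gradient arriving
        at the *output* of layer ``stop_after - 1`` (i.e. gradients flow through
        layers ``stop_after .. end``)."""
        for layer in reversed(self.layers[stop_after:]):
            dy = layer.backward(dy)
        return dy

    def activations(self, x: np.ndarray) -> list[np.ndarray]:
        """Forward pass returning every layer's output (inference mode)."""
        acts = []
        for layer in self.layers:
            x = layer.forward(x, train=False)
            acts.append(x)
        return acts

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [copy.deepcopy(w) for w, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        mine = self.params()
        if len(weights) != len(mine):
            raise ConfigurationError("weight list does not match network")
        for (w, _), new in zip(mine, weights):
            w[...] = new


class Adam:
    def __init__(self, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-7):
        self.lr, self.betas, self.eps = lr, betas, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, params) -> None:
        b1, b2 = self.betas
        self._t += 1
        for i, (w, g) in enumerate(params):
            m = self._m.setdefault(i, np.zeros_like(w))
            v = self._v.setdefault(i, np.zeros_like(w))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            w[...] = w - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.sum(onehot * np.log(np.maximum(p, 1e-12))) / n)
    return loss, ((p - onehot) / n).astype(np.float32)

def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred.reshape(-1) - target.reshape(-1)
    n = diff.size
    return float(np.mean(diff**2)), (2.0 * diff / n).reshape(pred.shape).astype(np.float32)
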
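"""Minimal NumPy neural-network core.

Implements exactly the pieces the tile models need: stride-2 2-D
convolutions (im2col), 2x2-stride-2 transposed convolutions for
mirror-image decoders, ReLU/sigmoid nonlinearities, dense heads, MSE and
binary-cross-entropy-with-logits losses, and the Adam optimizer. All
arrays are float32, layout ``(N, C, H, W)``. Forward passes cache what the
backward pass needs; ``Sequential`` chains layers and exposes flat
parameter access for checkpointing.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "mse_loss",
    "bce_with_logits",
]


class Layer:
    """Base class: stateless layers override forward/backward only."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution, He-initialized, arbitrary kernel/stride/padding."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * kernel * kernel))
        self.W = rng.normal(0.0, scale, (cout, cin, kernel, kernel)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :ho, :wo]            # (n,c,ho,wo,k,k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols)
        y = cols @ self.W.reshape(len(self.W), -1).T + self.b
        self._cache = (cols, (n, c, h, w), (ho, wo))
        return y.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        k, s, p = self.kernel, self.stride, self.pad
        cols, (n, c, h, w), (ho, wo) = self._cache
        cout = dy.shape[1]
        dy2 = dy.transpose(0, 2, 3, 1).reshape(n, ho * wo, cout)
        self.dW[:] = np.einsum("npo,npk->ok", dy2, cols).reshape(self.W.shape)
        self.db[:] = dy2.sum(axis=(0, 1))
        dcols = (dy2 @ self.W.reshape(cout, -1)).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        # scatter-add each kernel offset back onto the padded input grid
        for a in range(k):
            for b in range(k):
                dxp[:, :, a:a + s * ho:s, b:b + s * wo:s] += dcols[:, :, :, :, a, b].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2d(Layer):
    """2x2-kernel, stride-2 transposed convolution: exact x2 upsampling.

    Non-overlapping output patches make forward and backward simple
    einsums; used for the decoder mirror of stride-2 encoders.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * 4))
        self.W = rng.normal(0.0, scale, (cin, cout, 2, 2)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("ncij,coab->noiajb", x, self.W, optimize=True)
        return (y.reshape(n, self.W.shape[1], 2 * h, 2 * w)
                + self.b[None, :, None, None])

    def backward(self, dy):
        x = self._x
        n, cout = dy.shape[0], dy.shape[1]
        h, w = x.shape[2], x.shape[3]
        dyp = dy.reshape(n, cout, h, 2, w, 2)
        self.dW[:] = np.einsum("ncij,noiajb->coab", x, dyp, optimize=True)
        self.db[:] = dy.sum(axis=(0, 2, 3))
        return np.einsum("noiajb,coab->ncij", dyp, self.W, optimize=True)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    """Mean over spatial dims: (N,C,H,W) -> (N,C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / nin)
        self.W = rng.normal(0.0, scale, (nin, nout)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        """Deep copy of all parameters, for checkpointing."""
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p[:] = s


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        b1, b2 = self.betas
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element; returns (loss, dloss/dpred)."""
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    return loss, (2.0 / diff.size) * diff


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross entropy on logits; numerically stable log1p form."""
    z = logits.astype(np.float64).ravel()
    t = y.astype(np.float64).ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - t) / z.size).astype(np.float32).reshape(logits.shape)
    return loss, grad


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference gradient, used only by the test suite."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


def copy_model(model: Sequential) -> Sequential:
    return copy.deepcopy(model)
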
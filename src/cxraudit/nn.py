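"""Minimal dense/convolutional network layers with explicit backpropagation.

All arrays are float64 numpy; image batches use the (N, C, H, W) layout.
Every layer caches what its backward pass needs during ``forward``, so a
``backward`` call must follow the matching ``forward`` before the layer is
used again.  ``Sequential.backward`` both accumulates parameter gradients
and returns the gradient with respect to the network input, which is what
path-attribution methods differentiate.

Everything here is deterministic given the numpy Generator used at
construction time; there is no hidden global state.
"""

from __future__ import annotations

import numpy as np

from .errors import NumericError

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "Dense",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Flatten",
    "GlobalAvgPool",
    "SigmoidSqueeze",
    "Sequential",
    "SGD",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def bce_with_logits(z: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross entropy over all elements.

    Returns ``(loss, dloss/dz)``.  Uses the softplus form
    ``BCE = softplus(z) - t*z`` which is stable for large |z|.
    """
    zc = np.clip(z, -60.0, 60.0)
    loss = float(np.mean(np.logaddexp(0.0, zc) - t * zc))
    grad = (sigmoid(zc) - t) / z.size
    return loss, grad


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "frozen")

    def __init__(self, value: np.ndarray, frozen: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.frozen = frozen


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int):
    """(N, C, H, W) -> column matrix (N*Ho*Wo, C*k*k) plus output geometry."""
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # (N, C, Ho, Wo, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col, square kernel."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 weight_scale: float | None = None, frozen: bool = False):
        rng = rng or np.random.default_rng(0)
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin * k * k)), frozen)
        self.b = Param(np.zeros(cout), frozen)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        if self.pad:
            p = self.pad
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        cols, ho, wo = _im2col(xp, self.k, self.stride)
        out = cols @ self.w.value.T + self.b.value
        n = x.shape[0]
        self._cache = (cols, xp.shape, ho, wo)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xp_shape, ho, wo = self._cache
        n, _, hp, wp = xp_shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        if not self.w.frozen:
            self.w.grad += dflat.T @ cols
            self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.w.value                      # (N*Ho*Wo, C*k*k)
        dcols = dcols.reshape(n, ho, wo, self.cin, self.k, self.k)
        dxp = np.zeros(xp_shape)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            p = self.pad
            return dxp[:, :, p:hp - p, p:wp - p]
        return dxp


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None,
                 weight_scale: float | None = None, frozen: bool = False):
        rng = rng or np.random.default_rng(0)
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / nin)
        self.w = Param(rng.normal(0.0, scale, size=(nout, nin)), frozen)
        self.b = Param(np.zeros(nout), frozen)
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout):
        if not self.w.frozen:
            self.w.grad += dout.T @ self._x
            self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y ** 2)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) by spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class SigmoidSqueeze(Layer):
    """(N, 1) logits -> (N,) probabilities."""

    def forward(self, x):
        self._p = sigmoid(x[:, 0])
        return self._p

    def backward(self, dout):
        return (dout * self._p * (1.0 - self._p))[:, None]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        if not np.all(np.isfinite(x)):
            raise NumericError("non-finite activations in forward pass")
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v


class SGD:
    """SGD with momentum and decoupled-from-loss L2 weight decay.

    Matches the usual deep-learning convention: ``g <- g + wd * w``,
    ``v <- mu * v + g``, ``w <- w - lr * v``.
    """

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if not p.frozen]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if not p.frozen]
        self.lr, self.betas, self.eps = lr, betas, eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
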
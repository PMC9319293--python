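"""Minimal seeded neural-network layers on numpy.

Implements exactly the pieces the two image models need — 3x3 same-padding
convolutions, batch normalization, ReLU, 2x2 max pooling, dropout, dense
layers and a softmax cross-entropy head — with SGD and Adam optimizers.
Everything is deterministic given the rng handed to it and runs on one CPU
core.  Backward passes are verified against numerical gradients in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2x2",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "SGD",
    "Adam",
    "softmax",
    "cross_entropy_grad",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss of softmax(logits) against integer labels
    and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Layer:
    trainable = True

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) convolution with 'same' zero padding, stride 1, via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self._gW = np.zeros_like(self.W)
        self._gb = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self._gW, self._gb]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        n, c, h, w = x.shape
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)

    def forward(self, x, train):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        n, c, h, w = x.shape
        out = self._cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, g):
        n, c_out, h, w = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
        self._gW[...] = (gmat.T @ self._cols).reshape(self.W.shape)
        self._gb[...] = gmat.sum(axis=0)
        gcols = gmat @ self.W.reshape(c_out, -1)
        # col2im: scatter-add windows back onto the padded grid
        k = self.k
        p = k // 2
        _, c_in, hh, ww = self._x_shape
        gx = np.zeros((n, c_in, hh + 2 * p, ww + 2 * p))
        gcols = gcols.reshape(n, h, w, c_in, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + h, dj:dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return gx[:, :, p:p + hh, p:p + ww]


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self._gg = np.zeros_like(self.gamma)
        self._gb = np.zeros_like(self.beta)

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def grads(self):
        return [self._gg, self._gb]

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, g):
        axes = (0, 2, 3)
        self._gg[...] = (g * self._xhat).sum(axis=axes)
        self._gb[...] = g.sum(axis=axes)
        gxhat = g * self.gamma[None, :, None, None]
        if not self._train:
            return gxhat / self._std
        m = g.shape[0] * g.shape[2] * g.shape[3]
        return (gxhat - gxhat.mean(axis=axes, keepdims=True)
                - self._xhat * (gxhat * self._xhat).mean(axis=axes, keepdims=True)) / self._std


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2, no padding (even spatial dims required)."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        self._xr_shape = xr.shape
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, g):
        n, c, ho, wo = g.shape
        flat = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(flat, self._argmax[..., None], g[..., None], axis=-1)
        xr = flat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return xr.reshape(n, c, ho * 2, wo * 2)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self._gW = np.zeros_like(self.W)
        self._gb = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self._gW, self._gb]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self._gW[...] = self._x.T @ g
        self._gb[...] = g.sum(axis=0)
        return g @ self.W.T


class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def attach(self, params):
        pass

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None

    def attach(self, params):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params, grads):
        if self.m is None:
            self.attach(params)
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Sequential:
    """A plain layer stack with softmax cross-entropy training."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch):
            out.append(softmax(self.forward(x[i:i + batch], train=False)))
        return np.vstack(out) if out else np.zeros((0, 2))

    def fit(self, x: np.ndarray, y: np.ndarray, *, optimizer, epochs: int,
            batch_size: int, rng: np.random.Generator,
            log: list[dict] | None = None) -> "Sequential":
        optimizer.attach(self.params)
        n = len(x)
        for epoch in range(epochs):
            order = rng.permutation(n)
            total, correct, seen = 0.0, 0, 0
            for i in range(0, n, batch_size):
                idx = order[i:i + batch_size]
                logits = self.forward(x[idx], train=True)
                loss, g = cross_entropy_grad(logits, y[idx])
                self.backward(g)
                optimizer.step(self.params, self.grads)
                total += loss * len(idx)
                correct += int((logits.argmax(axis=1) == y[idx]).sum())
                seen += len(idx)
            if log is not None:
                log.append({"epoch": epoch, "loss": total / seen, "acc": correct / seen})
        return self
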
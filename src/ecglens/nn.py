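"""Minimal differentiable 1-D CNN engine in numpy.

Implements exactly the layer set the residual ECG network needs —
1-D convolution (im2col over BLAS matmul), batch normalization, ReLU,
average pooling, dropout, global average pooling and a dense head — each
with an explicit backward pass, plus the Nadam optimizer.  The engine
exposes every named intermediate feature map and its gradient, which is
what gradient-weighted class-activation mapping requires.

All computation is float32.  Shapes follow the (batch, channels, length)
convention.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv1D", "BatchNorm1D", "ReLU", "AvgPool1D", "Dropout",
           "GlobalAvgPool", "Dense", "Nadam",
           "mse_loss", "bce_with_logits_loss"]


class Layer:
    """Base class: parameters, gradients, forward/backward."""

    def __init__(self, name: str):
        self.name = name
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}
        self.stats: Dict[str, np.ndarray] = {}   # non-trainable state

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self, include_nontrainable: bool = False) -> int:
        n = sum(p.size for p in self.params.values())
        if include_nontrainable:
            n += sum(s.size for s in self.stats.values())
        return n

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def _glorot_uniform(rng: np.random.Generator, shape: Tuple[int, ...],
                    fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D(Layer):
    """Same-padded 1-D convolution, stride 1, with bias.

    Weight shape ``(c_out, c_in, k)``; for even kernels the extra padding
    sample goes on the right (TensorFlow 'SAME' convention).
    """

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: Optional[np.random.Generator] = None, name: str = "conv"):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pl = (k - 1) // 2
        self.pr = k - 1 - self.pl
        self.params["W"] = _glorot_uniform(rng, (c_out, c_in, k),
                                           fan_in=c_in * k, fan_out=c_out * k)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cols: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        if C != self.c_in:
            raise ValueError(f"{self.name}: expected {self.c_in} channels, got {C}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pl, self.pr)))
        win = sliding_window_view(xp, self.k, axis=2)        # (B, C, L, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)
                                    ).reshape(B * L, C * self.k)
        W2 = self.params["W"].reshape(self.c_out, C * self.k)
        y = cols @ W2.T + self.params["b"]
        self._cols = cols if training else None
        self._BL = (B, L)
        return np.ascontiguousarray(y.reshape(B, L, self.c_out).transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L = self._BL
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * L, self.c_out)
        if self._cols is not None:
            dW2 = dy2.T @ self._cols                         # (c_out, C*k)
            self.grads["W"] = self.grads.get(
                "W", 0) + dW2.reshape(self.params["W"].shape)
            self.grads["b"] = self.grads.get("b", 0) + dy2.sum(axis=0)
        # dx: full correlation of dy with the kernel flipped along k.
        dyp = np.pad(dy, ((0, 0), (0, 0), (self.pr, self.pl)))
        win = sliding_window_view(dyp, self.k, axis=2)       # (B, c_out, L, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)
                                    ).reshape(B * L, self.c_out * self.k)
        Wf = self.params["W"][:, :, ::-1]                    # (c_out, c_in, k)
        Wf2 = np.ascontiguousarray(Wf.transpose(0, 2, 1)).reshape(
            self.c_out * self.k, self.c_in)
        dx = cols @ Wf2
        return np.ascontiguousarray(dx.reshape(B, L, self.c_in).transpose(0, 2, 1))


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, time).

    Keras-style defaults: momentum 0.99, epsilon 1e-3.  Evaluation mode
    uses the moving statistics, so inference is deterministic and its
    backward pass is a simple per-channel rescale.
    """

    def __init__(self, c: int, momentum: float = 0.99, eps: float = 1e-3,
                 name: str = "bn"):
        super().__init__(name)
        self.c, self.momentum, self.eps = c, momentum, eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.stats["moving_mean"] = np.zeros(c, dtype=np.float32)
        self.stats["moving_var"] = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        g = self.params["gamma"][:, None]
        b = self.params["beta"][:, None]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.stats["moving_mean"] = (m * self.stats["moving_mean"]
                                         + (1 - m) * mean).astype(np.float32)
            self.stats["moving_var"] = (m * self.stats["moving_var"]
                                        + (1 - m) * var).astype(np.float32)
        else:
            mean = self.stats["moving_mean"]
            var = self.stats["moving_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * ivar[:, None]
        self._cache = (xhat, ivar.astype(np.float32), training, x.shape)
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, training, shape = self._cache
        g = self.params["gamma"]
        self.grads["gamma"] = self.grads.get(
            "gamma", 0) + (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"] = self.grads.get("beta", 0) + dy.sum(axis=(0, 2))
        dxhat = dy * g[:, None]
        if not training:
            return dxhat * ivar[:, None]
        B, C, L = shape
        n = B * L
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (ivar[:, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        super().__init__(name)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class AvgPool1D(Layer):
    """Non-overlapping average pooling; an odd trailing sample is dropped."""

    def __init__(self, pool: int = 2, name: str = "pool"):
        super().__init__(name)
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        Lo = L // self.pool
        self._L = L
        return x[:, :, :Lo * self.pool].reshape(B, C, Lo, self.pool).mean(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, Lo = dy.shape
        dx = np.zeros((B, C, self._L), dtype=dy.dtype)
        dx[:, :, :Lo * self.pool] = np.repeat(dy / self.pool, self.pool, axis=2)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, name: str = "drop"):
        super().__init__(name)
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class GlobalAvgPool(Layer):
    def __init__(self, name: str = "gap"):
        super().__init__(name)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._L, axis=2) / self._L


class Dense(Layer):
    """Fully connected layer on (batch, features)."""

    def __init__(self, c_in: int, c_out: int = 1,
                 rng: Optional[np.random.Generator] = None, name: str = "head"):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _glorot_uniform(rng, (c_in, c_out), c_in, c_out)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self.grads.get("W", 0) + self._x.T @ dy
        self.grads["b"] = self.grads.get("b", 0) + dy.sum(axis=0)
        return dy @ self.params["W"].T


class Nadam:
    """Nesterov-momentum Adam (Keras-default hyperparameters)."""

    def __init__(self, layers: List[Layer], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {(id(l), k): np.zeros_like(p)
                  for l in self.layers for k, p in l.params.items()}
        self.v = {(id(l), k): np.zeros_like(p)
                  for l in self.layers for k, p in l.params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for layer in self.layers:
            for k, p in layer.params.items():
                g = layer.grads[k]
                key = (id(layer), k)
                m = self.m[key] = b1 * self.m[key] + (1 - b1) * g
                v = self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
                mhat = m / c1
                vhat = v / c2
                update = (b1 * mhat + (1 - b1) * g / c1) / (np.sqrt(vhat) + self.eps)
                p -= (self.lr * update).astype(p.dtype)


def mse_loss(pred: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    r = pred - y
    return float(np.mean(r * r)), (2.0 * r / r.size).astype(np.float32)


def bce_with_logits_loss(z: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Binary cross-entropy on logits (numerically stable) and its gradient."""
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, ((p - y) / z.size).astype(np.float32)
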
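"""Minimal feed-forward building blocks with explicit reverse-mode gradients.

Everything operates on float32 2D batches ``(rows, channels)``; the point-set
model reshapes ``(batch, n_points, channels)`` to rows before the shared
per-point layers. Layers cache what their backward pass needs, so the usage
pattern is strictly forward -> backward -> optimizer step.
"""

from __future__ import annotations

import numpy as np

try:  # fused batchnorm+ReLU kernels; the numpy fallback is semantically identical
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


__all__ = [
    "Param",
    "Dense",
    "BatchNorm",
    "relu",
    "relu_backward",
    "Adam",
    "HAVE_NUMBA",
    "bn_batch_stats",
    "bn_relu_forward",
    "bn_relu_backward",
]


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Dense:
    """Affine map ``y = x @ W + b`` with He-style initialization."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        weight_scale: float | None = None,
        bias_init: float = 0.0,
    ):
        scale = np.sqrt(2.0 / n_in) if weight_scale is None else weight_scale
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.full(n_out, bias_init, dtype=np.float32))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class BatchNorm:
    """Batch normalization over axis 0 with learned scale/shift.

    Running statistics (exponential moving average, momentum 0.9) are used at
    inference time, making evaluation deterministic and independent of batch
    composition.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_channels, dtype=np.float32))
        self.beta = Param(np.zeros(n_channels, dtype=np.float32))
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            xhat = x - mean
            var = np.einsum("ij,ij->j", xhat, xhat) / x.shape[0]
            inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            xhat *= inv_std
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
            self._cache = (xhat, inv_std)
            return xhat * self.gamma.value + self.beta.value
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * (self.gamma.value * inv_std) + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # dx = gamma*inv_std * (dy - mean(dy) - xhat * mean(dy*xhat));
        # written to touch each (rows, C) array as few times as possible
        xhat, inv_std = self._cache
        m = dy.shape[0]
        sum_dy = dy.sum(axis=0)
        sum_dy_xhat = np.einsum("ij,ij->j", dy, xhat)
        self.gamma.grad += sum_dy_xhat
        self.beta.grad += sum_dy
        c = self.gamma.value * inv_std
        dx = dy * c
        dx -= xhat * (c * sum_dy_xhat / m)
        dx -= c * sum_dy / m
        return dx


@njit(cache=True, fastmath=True)
def bn_batch_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and (population) variance in a single pass over rows."""
    m, c = x.shape
    s = np.zeros(c, dtype=np.float64)
    q = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            v = x[i, j]
            s[j] += v
            q[j] += v * v
    mean = s / m
    var = q / m - mean * mean
    return mean.astype(np.float32), np.maximum(var, 0.0).astype(np.float32)


@njit(cache=True, fastmath=True)
def bn_relu_forward(
    x: np.ndarray,
    mean: np.ndarray,
    inv_std: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    out: np.ndarray,
) -> None:
    """Normalize ``x`` in place (it becomes xhat) and write relu(gamma*xhat+beta)."""
    m, c = x.shape
    for i in range(m):
        for j in range(c):
            xh = (x[i, j] - mean[j]) * inv_std[j]
            x[i, j] = xh
            v = xh * gamma[j] + beta[j]
            out[i, j] = v if v > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def bn_relu_backward(
    dy: np.ndarray,
    out: np.ndarray,
    xhat: np.ndarray,
    coef: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fused relu-mask + batchnorm backward, in place on ``dy``.

    ``coef = gamma * inv_std``. Returns (sum of masked dy, sum of masked
    dy * xhat) = the beta and gamma gradients.
    """
    m, c = dy.shape
    s1 = np.zeros(c, dtype=np.float64)
    s2 = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            d = dy[i, j] if out[i, j] > 0.0 else 0.0
            dy[i, j] = d
            s1[j] += d
            s2[j] += d * xhat[i, j]
    k1 = (s1 / m).astype(np.float32)
    k2 = (s2 / m).astype(np.float32)
    for i in range(m):
        for j in range(c):
            dy[i, j] = coef[j] * (dy[i, j] - k1[j] - xhat[i, j] * k2[j])
    return s1.astype(np.float32), s2.astype(np.float32)


@njit(cache=True, fastmath=False)
def _maxpool_points_numba(feats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b, n, c = feats.shape
    pooled = feats[:, 0, :].copy()
    arg = np.zeros((b, c), dtype=np.int64)
    for i in range(b):
        for j in range(1, n):
            for k in range(c):
                v = feats[i, j, k]
                if v > pooled[i, k]:
                    pooled[i, k] = v
                    arg[i, k] = j
    return pooled, arg


def maxpool_points(feats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Channel-wise max over the point axis of ``(B, N, C)``.

    Returns (pooled ``(B, C)``, index of the first maximum ``(B, C)``); the
    index routes gradients in the backward pass.
    """
    if HAVE_NUMBA:
        return _maxpool_points_numba(feats)
    arg = feats.argmax(axis=1)
    return np.take_along_axis(feats, arg[:, None, :], axis=1)[:, 0, :], arg


def relu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rectifier; returns (output, mask) where mask gates the backward pass."""
    mask = x > 0
    return np.maximum(x, 0.0), mask


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


class Adam:
    """Adaptive-moment optimizer (Kingma & Ba) over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        learning_rate: float = 0.01,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
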
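"""Minimal seeded NumPy layers with explicit forward/backward passes.

The networks in this package are small (a few mega-FLOPs per image), so a
plain NumPy implementation with im2col convolutions is fast enough on one
CPU and — unlike GPU frameworks — bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv2d",
    "LocallyConnected1x1",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Flatten",
    "softmax",
    "softmax_cross_entropy",
]


#: Network-wide dtype; float32 halves memory traffic and is plenty for SGD.
DTYPE = np.float32


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-style initialization: N(0, 2 / fan_in), fan-in scaling."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Layer:
    """Base layer: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        #: parameter names subject to weight decay (weights, not biases/BN)
        self.decayed: set[str] = set()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": he_normal(rng, (n_in, n_out), n_in),
            "b": np.zeros(n_out, dtype=DTYPE),
        }
        self.decayed = {"W"}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T


class Conv2d(Layer):
    """kxk convolution, stride 1, 'same' zero padding.

    Implemented as k*k shifted (n*h*w, c_in) @ (c_in, c_out) matmuls, which
    avoids materializing the im2col matrix and keeps BLAS busy.  Weights
    are stored as (k, k, c_in, c_out).
    """

    def __init__(
        self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        fan_in = c_in * kernel * kernel
        self.params = {
            "W": he_normal(rng, (kernel, kernel, c_in, c_out), fan_in),
            "b": np.zeros(c_out, dtype=DTYPE),
        }
        self.decayed = {"W"}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, pad = self.kernel, self.kernel // 2
        n, c, h, w = x.shape
        self._shape = x.shape
        # channels-last padded copy; each kernel tap is one flat matmul
        xp = np.pad(x.transpose(0, 2, 3, 1), ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        self._xp = xp
        W = self.params["W"]
        out = np.zeros((n * h * w, self.c_out), dtype=np.result_type(xp, W))
        for i in range(k):
            for j in range(k):
                tap = np.ascontiguousarray(xp[:, i : i + h, j : j + w, :]).reshape(
                    n * h * w, c
                )
                out += tap @ W[i, j]
        out += self.params["b"]
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, pad = self.kernel, self.kernel // 2
        n, c, h, w = self._shape
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.c_out
        )
        W = self.params["W"]
        dW = np.empty_like(W)
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            for j in range(k):
                tap = np.ascontiguousarray(
                    self._xp[:, i : i + h, j : j + w, :]
                ).reshape(n * h * w, c)
                dW[i, j] = tap.T @ dy_flat
                dxp[:, i : i + h, j : j + w, :] += (dy_flat @ W[i, j].T).reshape(
                    n, h, w, c
                )
        self.grads = {"W": dW, "b": dy_flat.sum(axis=0)}
        return dxp[:, pad : pad + h, pad : pad + w, :].transpose(0, 3, 1, 2)


class LocallyConnected1x1(Layer):
    """Position-specific (unshared) 1x1 filters: per-pixel channel mixing."""

    def __init__(
        self, c_in: int, c_out: int, h: int, w: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.h, self.w, self.c_in, self.c_out = h, w, c_in, c_out
        self.params = {
            "W": he_normal(rng, (h * w, c_in, c_out), c_in),
            "b": np.zeros((h * w, c_out), dtype=DTYPE),
        }
        self.decayed = {"W"}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n = x.shape[0]
        # (n, c, h, w) -> (p, n, c): one batched matmul per grid position
        self._xp = np.ascontiguousarray(
            x.reshape(n, self.c_in, self.h * self.w).transpose(2, 0, 1)
        )
        out = np.matmul(self._xp, self.params["W"])  # (p, n, c_out)
        out += self.params["b"][:, None, :]
        return out.transpose(1, 2, 0).reshape(n, self.c_out, self.h, self.w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        dyp = np.ascontiguousarray(
            dy.reshape(n, self.c_out, self.h * self.w).transpose(2, 0, 1)
        )  # (p, n, c_out)
        self.grads = {
            "W": np.matmul(self._xp.transpose(0, 2, 1), dyp),
            "b": dyp.sum(axis=1),
        }
        dxp = np.matmul(dyp, self.params["W"].transpose(0, 2, 1))  # (p, n, c_in)
        return dxp.transpose(1, 2, 0).reshape(n, self.c_in, self.h, self.w)


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial axes for 4-D input).

    Running statistics are exponential moving averages at training time and
    can be wholesale recomputed from any sample via calibration mode.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(n_features, dtype=DTYPE),
            "beta": np.zeros(n_features, dtype=DTYPE),
        }
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.calibrating = False
        self._cal_n = 0
        self._cal_sum = np.zeros(n_features)
        self._cal_sumsq = np.zeros(n_features)

    def _axes(self, x: np.ndarray) -> tuple[int, ...]:
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _expand(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v if ndim == 2 else v[None, :, None, None]

    def begin_calibration(self) -> None:
        self.calibrating = True
        self._cal_n = 0
        self._cal_sum = np.zeros_like(self.running_mean)
        self._cal_sumsq = np.zeros_like(self.running_var)

    def end_calibration(self) -> None:
        if self._cal_n < 2:
            raise ValueError("calibration requires at least two samples")
        mean = self._cal_sum / self._cal_n
        var = self._cal_sumsq / self._cal_n - mean**2
        self.running_mean = mean.astype(DTYPE)
        self.running_var = np.maximum(var, 0.0).astype(DTYPE)
        self.calibrating = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = self._axes(x)
        if self.calibrating:
            n = int(np.prod([x.shape[a] for a in axes]))
            self._cal_n += n
            self._cal_sum += x.sum(axis=axes)
            self._cal_sumsq += (x**2).sum(axis=axes)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
        elif train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean
            var = self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - self._expand(mean, x.ndim)) / self._expand(self._std, x.ndim)
        self._train = train and not self.calibrating
        return (
            self._expand(self.params["gamma"], x.ndim) * self._xhat
            + self._expand(self.params["beta"], x.ndim)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = self._axes(dy)
        m = np.prod([dy.shape[a] for a in axes])
        self.grads = {
            "gamma": (dy * self._xhat).sum(axis=axes),
            "beta": dy.sum(axis=axes),
        }
        g = self._expand(self.params["gamma"], dy.ndim)
        std = self._expand(self._std, dy.ndim)
        if not self._train:
            return dy * (g / std)
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=axes)
        mean_dxhat_xhat = (dxhat * self._xhat).sum(axis=axes) / m
        # in-place: dx = (dxhat - mean(dxhat) - xhat * mean(dxhat*xhat)) / std
        dxhat -= self._expand(mean_dxhat, dy.ndim)
        dxhat -= self._xhat * self._expand(mean_dxhat_xhat, dy.ndim)
        dxhat /= std
        return dxhat


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, x.dtype.type(0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        np.multiply(dy, self._mask, out=dy)
        return dy


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(
            x.dtype
        )
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n
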
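"""Minimal NumPy neural-network building blocks.

Layers cache what their backward pass needs, accumulate parameter gradients
in ``.grads`` and return the gradient w.r.t. their input.  Everything is
deterministic given the RNG passed in, which is what makes training runs
bitwise reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "Linear",
    "ReLU",
    "Dropout",
    "GlobalAvgPool",
    "SGDM",
    "softmax",
    "one_hot",
]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


class Layer:
    """Base: trainable arrays in ``params``, matching grads in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(N, C, H, W) -> (N, C*k*k, H_out*W_out) patch matrix."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    h_out = (h + 2 * pad - k) // stride + 1
    w_out = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, h_out, w_out), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride]
    return cols.reshape(n, c * k * k, h_out * w_out), h_out, w_out


def _col2im(
    cols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int, pad: int
) -> np.ndarray:
    n, c, h, w = x_shape
    h_out = (h + 2 * pad - k) // stride + 1
    w_out = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, h_out, w_out)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * h_out : stride, j : j + stride * w_out : stride] += cols[
                :, :, i, j
            ]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Conv2d(Layer):
    """k x k convolution with zero padding, evaluated via im2col."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        k: int = 3,
        stride: int = 2,
        pad: int = 1,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k, self.stride, self.pad = k, stride, pad
        fan_in = in_channels * k * k
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, k, k))
        self.params["b"] = np.zeros(out_channels)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        cols, h_out, w_out = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        w_mat = self.params["W"].reshape(self.out_channels, -1)
        y = np.matmul(w_mat, cols) + self.params["b"][None, :, None]
        return y.reshape(x.shape[0], self.out_channels, h_out, w_out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n = gout.shape[0]
        g = gout.reshape(n, self.out_channels, -1)
        gw = np.matmul(g, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["W"] += gw.reshape(self.params["W"].shape)
        self.grads["b"] += g.sum(axis=(0, 2))
        w_mat = self.params["W"].reshape(self.out_channels, -1)
        gcols = np.matmul(w_mat.T, g)
        return _col2im(gcols, self._x_shape, self.k, self.stride, self.pad)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_features), (out_features, in_features))
        self.params["b"] = np.zeros(out_features)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads["W"] += gout.T @ self._x
        self.grads["b"] += gout.sum(axis=0)
        return gout @ self.params["W"]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout if self._mask is None else gout * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None], self._shape) / (h * w)


class SGDM:
    """Stochastic gradient descent with momentum: v <- mu v - eta g; W <- W + v."""

    def __init__(self, layers: list[Layer], lr: float, momentum: float = 0.9) -> None:
        self.layers = layers
        self.lr = lr
        self.momentum = momentum
        self.velocity = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def step(self) -> None:
        for layer, vel in zip(self.layers, self.velocity):
            for k in layer.params:
                vel[k] = self.momentum * vel[k] - self.lr * layer.grads[k]
                layer.params[k] += vel[k]
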
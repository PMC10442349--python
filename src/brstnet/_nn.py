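"""Minimal NumPy neural-network core used by the expression models.

Implements exactly what the desk-scale convolutional regressors need: strided
2-D convolution via im2col, ReLU, global average pooling, fully connected
layers, mean-squared-error gradients, and SGD with momentum and decoupled-free
(classic L2) weight decay.  All computation is float32 and fully deterministic
given a seeded ``numpy.random.Generator``.

This is not a general autodiff framework; each layer caches what its own
backward pass needs and gradients are threaded manually by the model.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np


class Layer:
    """Base class: forward caches, backward consumes the cache once."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """Strided 2-D convolution with zero padding, via im2col."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.params = {
            "W": _he_init(rng, (fan_in, out_ch), fan_in),
            "b": np.zeros(out_ch, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        b, c, h, w = x.shape
        k, s = self.kernel, self.stride
        if self.pad:
            x = np.pad(
                x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad))
            )
        hp, wp = x.shape[2], x.shape[3]
        oh = (hp - k) // s + 1
        ow = (wp - k) // s + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s]  # (b, c, oh, ow, k, k)
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * oh * ow, c * k * k)
        return np.ascontiguousarray(cols, dtype=np.float32), (b, oh, ow, hp, wp)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols, (b, oh, ow, hp, wp) = self._im2col(x)
        out = cols @ self.params["W"] + self.params["b"]
        if train:
            self._cache = (cols, x.shape, (b, oh, ow, hp, wp))
        return out.reshape(b, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, (b, oh, ow, hp, wp) = self._cache
        k, s = self.kernel, self.stride
        g = grad.transpose(0, 2, 3, 1).reshape(b * oh * ow, self.out_ch)
        g = np.ascontiguousarray(g, dtype=np.float32)
        self.grads["W"][...] = cols.T @ g
        self.grads["b"][...] = g.sum(axis=0)
        dcols = g @ self.params["W"].T  # (b*oh*ow, c*k*k)
        dcols = dcols.reshape(b, oh, ow, self.in_ch, k, k)
        dx = np.zeros((b, self.in_ch, hp, wp), dtype=np.float32)
        # scatter-add each kernel offset back onto the padded input grid
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + oh * s : s, j : j + ow * s : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if self.pad:
            dx = dx[:, :, self.pad : hp - self.pad, self.pad : wp - self.pad]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), (b, c, h, w)
        ).astype(np.float32)


class Linear(Layer):
    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": _he_init(rng, (in_dim, out_dim), in_dim),
            "b": np.zeros(out_dim, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad.astype(np.float32)
        self.grads["W"][...] = self._x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Sequential(Layer):
    def __init__(self, layers: Iterable[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.parameters())
            else:
                out.extend((layer, name) for name in layer.params)
        return out


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff.astype(np.float32)


def smooth_l1(
    pred: np.ndarray, target: np.ndarray, beta: float = 1.0
) -> tuple[float, np.ndarray]:
    """Huber-style smooth L1 over all elements and its gradient."""
    diff = pred - target
    absd = np.abs(diff)
    quad = absd < beta
    loss = float(
        np.mean(np.where(quad, 0.5 * diff * diff / beta, absd - 0.5 * beta))
    )
    grad = np.where(quad, diff / beta, np.sign(diff)) / diff.size
    return loss, grad.astype(np.float32)


LOSS_FNS = {"mse": mse, "smooth_l1": smooth_l1}


class SGD:
    """SGD with classic momentum and L2 weight decay (decay added to the
    gradient, matching the usual framework semantics)."""

    def __init__(
        self,
        parameters: list[tuple[Layer, str]],
        lr: float = 0.001,
        momentum: float = 0.9,
        weight_decay: float = 1e-4,
    ) -> None:
        self.parameters = parameters
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [
            np.zeros_like(layer.params[name]) for layer, name in parameters
        ]

    def step(self) -> None:
        for (layer, name), vel in zip(self.parameters, self._velocity):
            g = layer.grads[name]
            if self.weight_decay and name == "W":
                g = g + self.weight_decay * layer.params[name]
            vel *= self.momentum
            vel += g
            layer.params[name] -= np.float32(self.lr) * vel

    def zero_grad(self) -> None:
        for layer, name in self.parameters:
            layer.grads[name][...] = 0.0


class ReduceLROnPlateau:
    """Multiply the optimizer's learning rate by ``factor`` after ``patience``
    epochs without improvement of the monitored value."""

    def __init__(
        self,
        optimizer: SGD,
        factor: float = 0.1,
        patience: int = 10,
        min_lr: float = 1e-6,
    ) -> None:
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric: float) -> None:
        if metric < self.best - 1e-12:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                self.optimizer.lr = max(
                    self.optimizer.lr * self.factor, self.min_lr
                )
                self.num_bad = 0


def get_state(params: list[tuple[Layer, str]]) -> list[np.ndarray]:
    return [layer.params[name].copy() for layer, name in params]


def set_state(params: list[tuple[Layer, str]], state: list[np.ndarray]) -> None:
    for (layer, name), value in zip(params, state):
        layer.params[name][...] = value
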
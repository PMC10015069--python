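"""Minimal NumPy CNN engine: layers with explicit forward/backward passes.

Tensors are NCHW float64.  Convolutions use im2col (sliding-window view +
one GEMM) forward and a col2im scatter-add backward; max-pooling is 2x2
stride 2 with floor semantics (a trailing odd row/column receives no
gradient).  Everything is deterministic given the seeds used at init.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2x2",
    "GlobalAvgPool",
    "Linear",
    "Sigmoid",
    "Sequential",
    "SGD",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _init_weight(shape: tuple[int, ...], fan_in: int, scheme: str,
                 rng: np.random.Generator) -> np.ndarray:
    """'he' = Kaiming-normal (std sqrt(2/fan_in)), suited to ReLU stacks
    trained from scratch; 'narrow' = Gaussian std 0.01, the conventional
    init for a regression head attached to pretrained features."""
    if scheme == "he":
        std = math.sqrt(2.0 / fan_in)
    elif scheme == "narrow":
        std = 0.01
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    return rng.normal(0.0, std, size=shape)


class Conv2d(Layer):
    """2-D convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, init: str = "he", name: str = ""):
        if kernel % 2 != 1 or kernel < 1:
            raise ValueError(f"kernel size must be odd and positive, got {kernel}")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.weight = Param(
            _init_weight((out_ch, fan_in), fan_in, init, rng), f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), f"{name}.bias")
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N, H*W, C*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * self.k * self.k)
        self._cols, self._xshape = cols, x.shape
        y = cols @ self.weight.value.T + self.bias.value
        return y.transpose(0, 2, 1).reshape(n, self.out_ch, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = grad.shape
        g = grad.reshape(n, self.out_ch, h * w).transpose(0, 2, 1)  # N,HW,out
        cols = self._cols
        self.weight.grad += np.einsum("npo,npk->ok", g, cols)
        self.bias.grad += g.sum(axis=(0, 1))
        dcols = g @ self.weight.value  # N, HW, C*k*k
        k, p = self.k, self.k // 2
        c = self.in_ch
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2x2(Layer):
    """2x2 stride-2 max pooling with floor output size."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, :h2 * 2, :w2 * 2]
        blocks = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h2, w2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._inshape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dflat, self._argmax[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, c, h, w))
        dx[:, :, :h2 * 2, :w2 * 2] = (
            dflat.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class GlobalAvgPool(Layer):
    """NCHW -> NC per-channel spatial mean (the SE 'squeeze')."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._inshape).copy()


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 init: str = "he", name: str = ""):
        self.weight = Param(_init_weight((out_f, in_f), in_f, init, rng),
                            f"{name}.weight")
        self.bias = Param(np.zeros(out_f), f"{name}.bias")

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # 1/(1+e^-x) computed stably on both tails
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class SGD:
    """Stochastic gradient descent with classical momentum and decoupled-in
    -gradient L2 weight decay: v <- mu*v + (g + wd*w); w <- w - lr*v."""

    def __init__(self, params: Sequence[Param], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v
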
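"""Minimal CNN layer toolkit on NumPy arrays.

Feed-forward layers with explicit, hand-written backward passes — enough
to express the spectrogram classifiers used here (plain conv stacks,
residual bottlenecks, depthwise-separable and shuffle blocks,
squeeze-and-excitation) and to train the small ones on a CPU. Tensors are
NCHW float64. Every layer caches what its backward pass needs during
``forward``; ``backward(grad_out)`` returns the gradient with respect to
the layer input and accumulates parameter gradients in ``Param.grad``.

Batch-norm layers use batch statistics in training mode (running
statistics are tracked with momentum 0.1) and running statistics in eval
mode. Initialisation is Kaiming-normal for convolutions; an explicit
``numpy.random.Generator`` must be supplied, so model construction is
fully deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Module", "Conv2d", "BatchNorm2d", "ReLU", "ReLU6", "Sigmoid",
    "HardSigmoid", "HardSwish", "SiLU", "MaxPool2d", "GlobalAvgPool",
    "Sequential", "Residual", "ChannelShuffle", "ShuffleUnit", "SqueezeExcite",
    "Adam", "cosine_lr",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class; children and params are discovered from attributes."""

    training: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def children(self) -> Iterable["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Param]:
        out = [v for v in self.__dict__.values() if isinstance(v, Param)]
        for child in self.children():
            out.extend(child.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Conv2d(Module):
    """2-D convolution (cross-correlation), optionally grouped/depthwise."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        if in_ch % groups or out_ch % groups:
            raise ValueError("in_ch and out_ch must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.stride, self.pad, self.groups = stride, pad, groups
        fan_in = (in_ch // groups) * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, std, (out_ch, in_ch // groups, kernel, kernel)))
        self.bias = Param(np.zeros(out_ch)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p, g = self.kernel, self.stride, self.pad, self.groups
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, _, ho, wo = win.shape[:4]
        col = win.reshape(n, g, self.in_ch // g, ho, wo, k, k)
        w = self.weight.data.reshape(g, self.out_ch // g, self.in_ch // g, k, k)
        y = np.einsum("ngcijpq,gocpq->ngoij", col, w, optimize=True)
        y = y.reshape(n, self.out_ch, ho, wo)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = (x.shape, col)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, col = self._cache
        k, s, p, g = self.kernel, self.stride, self.pad, self.groups
        n, _, ho, wo = grad.shape
        gg = grad.reshape(n, g, self.out_ch // g, ho, wo)
        gw = np.einsum("ngoij,ngcijpq->gocpq", gg, col, optimize=True)
        self.weight.grad += gw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        w = self.weight.data.reshape(g, self.out_ch // g, self.in_ch // g, k, k)
        hp, wp = x_shape[2] + 2 * p, x_shape[3] + 2 * p
        gxp = np.zeros((n, self.in_ch, hp, wp))
        for ki in range(k):
            for kj in range(k):
                contrib = np.einsum("ngoij,goc->ngcij", gg, w[:, :, :, ki, kj],
                                    optimize=True)
                contrib = contrib.reshape(n, self.in_ch, ho, wo)
                gxp[:, :, ki:ki + ho * s:s, kj:kj + wo * s:s] += contrib
        return gxp[:, :, p:hp - p, p:wp - p] if p else gxp


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + \
            self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.gamma.data[None, :, None, None]
        if not self.training:
            return gxhat / std[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        sum_g = gxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (gxhat - sum_g / m - xhat * sum_gx / m) / std[None, :, None, None]


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class ReLU6(Module):
    def forward(self, x):
        self._mask = (x > 0) & (x < 6)
        return np.clip(x, 0.0, 6.0)

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Module):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class HardSigmoid(Module):
    """relu6(x + 3) / 6."""

    def forward(self, x):
        self._x = x
        return np.clip(x + 3.0, 0.0, 6.0) / 6.0

    def backward(self, grad):
        return grad * (((self._x > -3) & (self._x < 3)) / 6.0)


class HardSwish(Module):
    """x * relu6(x + 3) / 6."""

    def forward(self, x):
        self._x = x
        return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0

    def backward(self, grad):
        x = self._x
        d = np.where(x <= -3, 0.0, np.where(x >= 3, 1.0, (2.0 * x + 3.0) / 6.0))
        return grad * d


class SiLU(Module):
    """x * sigmoid(x) (swish)."""

    def forward(self, x):
        self._x = x
        self._s = 1.0 / (1.0 + np.exp(-x))
        return x * self._s

    def backward(self, grad):
        s, x = self._s, self._x
        return grad * (s * (1.0 + x * (1.0 - s)))


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride or kernel, pad

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        self._argmax = flat.argmax(axis=-1)
        self._x_shape, self._xp_shape = x.shape, xp.shape
        return flat.max(axis=-1)

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.pad
        n, c, ho, wo = grad.shape
        gxp = np.zeros((n, c, self._xp_shape[2], self._xp_shape[3]))
        ni, ci, ii, ji = np.indices((n, c, ho, wo))
        ri = ii * s + self._argmax // k
        rj = ji * s + self._argmax % k
        np.add.at(gxp, (ni, ci, ri, rj), grad)
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        return gxp


class GlobalAvgPool(Module):
    """Spatial mean, (N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Residual(Module):
    """y = act(main(x) + shortcut(x)); identity shortcut when none given."""

    def __init__(self, main: Module, shortcut: Module | None = None,
                 activation: Module | None = None):
        self.main = main
        self.shortcut = shortcut
        self.activation = activation

    def forward(self, x):
        y = self.main(x) + (self.shortcut(x) if self.shortcut is not None else x)
        if self.activation is not None:
            y = self.activation(y)
        return y

    def backward(self, grad):
        if self.activation is not None:
            grad = self.activation.backward(grad)
        gx = self.main.backward(grad)
        gx = gx + (self.shortcut.backward(grad) if self.shortcut is not None else grad)
        return gx


class ChannelShuffle(Module):
    def __init__(self, groups: int):
        self.groups = groups

    def forward(self, x):
        n, c, h, w = x.shape
        g = self.groups
        return x.reshape(n, g, c // g, h, w).swapaxes(1, 2).reshape(n, c, h, w)

    def backward(self, grad):
        n, c, h, w = grad.shape
        g = self.groups
        return grad.reshape(n, c // g, g, h, w).swapaxes(1, 2).reshape(n, c, h, w)


class ShuffleUnit(Module):
    """ShuffleNetV2 building block (channel split / strided variants)."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        if stride == 1 and in_ch != out_ch:
            raise ValueError("stride-1 shuffle unit requires in_ch == out_ch")
        bf = out_ch // 2
        self.stride = stride
        if stride > 1:
            self.branch1 = Sequential(
                Conv2d(in_ch, in_ch, 3, stride, 1, groups=in_ch, rng=rng),
                BatchNorm2d(in_ch),
                Conv2d(in_ch, bf, 1, rng=rng), BatchNorm2d(bf), ReLU(),
            )
            b2_in = in_ch
        else:
            self.branch1 = None
            b2_in = bf
        self.branch2 = Sequential(
            Conv2d(b2_in, bf, 1, rng=rng), BatchNorm2d(bf), ReLU(),
            Conv2d(bf, bf, 3, stride, 1, groups=bf, rng=rng), BatchNorm2d(bf),
            Conv2d(bf, bf, 1, rng=rng), BatchNorm2d(bf), ReLU(),
        )
        self.shuffle = ChannelShuffle(2)

    def forward(self, x):
        if self.stride == 1:
            half = x.shape[1] // 2
            self._half = half
            x1, x2 = x[:, :half], x[:, half:]
            out = np.concatenate([x1, self.branch2(x2)], axis=1)
        else:
            out = np.concatenate([self.branch1(x), self.branch2(x)], axis=1)
        return self.shuffle(out)

    def backward(self, grad):
        grad = self.shuffle.backward(grad)
        half = grad.shape[1] // 2
        g1, g2 = grad[:, :half], grad[:, half:]
        if self.stride == 1:
            gx2 = self.branch2.backward(g2)
            return np.concatenate([g1, gx2], axis=1)
        return self.branch1.backward(g1) + self.branch2.backward(g2)


class SqueezeExcite(Module):
    """Channel attention: x * gate(fc2(act(fc1(GAP(x)))))."""

    def __init__(self, ch: int, reduced: int, rng: np.random.Generator,
                 act: Module | None = None, gate: Module | None = None):
        self.fc1 = Conv2d(ch, reduced, 1, bias=True, rng=rng)
        self.fc2 = Conv2d(reduced, ch, 1, bias=True, rng=rng)
        self.act = act or ReLU()
        self.gate = gate or Sigmoid()

    def forward(self, x):
        self._x = x
        z = x.mean(axis=(2, 3), keepdims=True)
        s = self.gate(self.fc2(self.act(self.fc1(z))))
        self._s = s
        return x * s

    def backward(self, grad):
        x, s = self._x, self._s
        gx = grad * s
        gs = (grad * x).sum(axis=(2, 3), keepdims=True)
        gz = self.fc1.backward(self.act.backward(self.fc2.backward(
            self.gate.backward(gs))))
        h, w = x.shape[2], x.shape[3]
        gx = gx + gz / (h * w)
        return gx


class Adam:
    """Adam optimiser over a list of :class:`Param`."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad ** 2 - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Cosine-annealed learning rate, lr0 at epoch 0 decaying towards 0."""
    if total_epochs < 1:
        raise ValueError("total_epochs must be >= 1")
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * epoch / total_epochs))
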
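"""Minimal reverse-mode autodiff on NumPy arrays for 2D encoder-decoders.

Only the operations the segmentation networks need are provided: same-size
3x3/1x1 convolution, 2x2 stride-2 transpose convolution, 2x2 max pooling,
ReLU, sigmoid, channel concatenation, broadcast multiplication and a
numerically stable Dice+BCE loss computed from logits. Convolutions use
``sliding_window_view`` + einsum (im2col) in both directions.

All parameters are float32; every random draw goes through an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "conv2d",
    "conv_transpose2d",
    "maxpool2x2",
    "relu",
    "sigmoid",
    "add",
    "mul",
    "concat",
    "scale",
    "mean_tensors",
    "dice_bce_from_logits",
    "Adam",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "_prev", "_backward", "requires_grad")

    def __init__(self, data: np.ndarray, prev: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None,
                 requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self._prev = prev
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)

    @property
    def size(self) -> int:
        return int(self.data.size)


# ---------------------------------------------------------------------------
# ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: int) -> Tensor:
    """Stride-1 2D convolution (cross-correlation) with symmetric padding."""
    kh, kw = w.data.shape[2], w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    out += b.data[None, :, None, None]
    t = Tensor(out, prev=(x, w, b))

    def backward(g: np.ndarray) -> None:
        if w.requires_grad:
            w._accumulate(np.einsum("nohw,nchwij->ocij", g, cols, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            q = kh - 1 - padding
            gp = np.pad(g, ((0, 0), (0, 0), (q, q), (q, q)))
            gcols = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            wf = w.data[:, :, ::-1, ::-1]
            x._accumulate(np.einsum("nohwij,ocij->nchw", gcols, wf, optimize=True))

    t._backward = backward
    return t


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 transpose convolution: doubles H and W.

    Weight layout is ``(C_in, C_out, 2, 2)``.
    """
    n, c, h, wd = x.data.shape
    co = w.data.shape[1]
    tmp = np.einsum("nchw,coab->nohawb", x.data, w.data, optimize=True)
    out = tmp.reshape(n, co, 2 * h, 2 * wd) + b.data[None, :, None, None]
    t = Tensor(out, prev=(x, w, b))

    def backward(g: np.ndarray) -> None:
        g6 = g.reshape(n, co, h, 2, wd, 2)
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nohawb->coab", x.data, g6, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(np.einsum("nohawb,coab->nchw", g6, w.data, optimize=True))

    t._backward = backward
    return t


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    t = Tensor(out, prev=(x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accumulate(gx.reshape(n, c, h, w))

    t._backward = backward
    return t


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    t = Tensor(np.where(mask, x.data, 0.0), prev=(x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * mask)

    t._backward = backward
    return t


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    t = Tensor(s, prev=(x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    t._backward = backward
    return t


def add(a: Tensor, b: Tensor) -> Tensor:
    t = Tensor(a.data + b.data, prev=(a, b))

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    t._backward = backward
    return t


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise product with broadcasting (used by attention gates)."""
    t = Tensor(a.data * b.data, prev=(a, b))

    def _reduce(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
        axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
        return g.sum(axis=axes, keepdims=True) if axes else g

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(_reduce(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_reduce(g * a.data, b.data.shape))

    t._backward = backward
    return t


def scale(x: Tensor, k: float) -> Tensor:
    t = Tensor(x.data * k, prev=(x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * k)

    t._backward = backward
    return t


def concat(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along the channel axis (axis 1)."""
    t = Tensor(np.concatenate([x.data for x in tensors], axis=1), prev=tuple(tensors))
    splits = np.cumsum([x.data.shape[1] for x in tensors])[:-1]

    def backward(g: np.ndarray) -> None:
        for x, gi in zip(tensors, np.split(g, splits, axis=1)):
            if x.requires_grad:
                x._accumulate(gi)

    t._backward = backward
    return t


def mean_tensors(tensors: Sequence[Tensor]) -> Tensor:
    """Arithmetic mean of same-shaped tensors (deep-supervision heads)."""
    k = 1.0 / len(tensors)
    out = sum(x.data for x in tensors) * k
    t = Tensor(out, prev=tuple(tensors))

    def backward(g: np.ndarray) -> None:
        for x in tensors:
            if x.requires_grad:
                x._accumulate(g * k)

    t._backward = backward
    return t


def dice_bce_from_logits(logits: Tensor, target: np.ndarray,
                         eps: float = 1e-6) -> Tensor:
    """Equally weighted soft-Dice + binary cross-entropy loss.

    Computed from logits for stability: the BCE gradient is
    ``(sigmoid(z) - y) / N`` and the Dice gradient is chained through
    ``p (1 - p)``.
    """
    z = np.clip(logits.data, -60, 60)
    y = np.asarray(target, dtype=np.float32)
    p = 1.0 / (1.0 + np.exp(-z))
    n = float(z.size)

    bce = float(np.mean(np.logaddexp(0.0, z) - y * z))
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum())
    dice = (2.0 * inter + eps) / (denom + eps)
    t = Tensor(np.float32(bce + (1.0 - dice)), prev=(logits,))

    def backward(g: np.ndarray) -> None:
        if logits.requires_grad:
            gb = (p - y) / n
            # d(1-dice)/dp = -(2 y (denom+eps) - (2 inter+eps)) / (denom+eps)^2
            gd = -(2.0 * y * (denom + eps) - (2.0 * inter + eps)) / (denom + eps) ** 2
            logits._accumulate(float(g) * (gb + gd * p * (1.0 - p)))

    t._backward = backward
    return t


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Parameter container with recursive traversal."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj) -> None:
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)

        visit(self)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """Biased stride-1 convolution; kernel 3 (padded) or 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are used")
        self.kernel = kernel
        self.padding = kernel // 2
        fan_in = c_in * kernel * kernel
        self.w = Parameter(_he_init(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.padding)


class ConvTranspose2d(Module):
    """Biased 2x2 stride-2 transpose convolution (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = Parameter(_he_init(rng, (c_in, c_out, 2, 2), c_in * 4))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.w, self.b)


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
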
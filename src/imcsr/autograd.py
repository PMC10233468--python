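"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the separation network and its losses
need: broadcasting arithmetic, matrix products, reductions, 2-D
convolution with same-padding (im2col), GELU and sigmoid activations,
and an Adam optimizer.  Everything is deterministic: there is no global
random state and no threading beyond what BLAS provides.

Gradients accumulate into ``Tensor.grad`` after calling
:meth:`Tensor.backward` on a scalar result.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "conv2d", "gelu", "sigmoid", "Adam"]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array with optional gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    # -- plumbing ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(x, like: "Tensor | None" = None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        # keep constants in the dtype of the tensor they combine with, so a
        # python-float scalar does not silently upcast a float32 graph
        if like is not None and arr.dtype != like.data.dtype:
            arr = arr.astype(like.data.dtype)
        return Tensor(arr)

    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (must be scalar if grad is None)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic --------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other, like=self)
        out_data = self.data + other.data

        def bw(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other, like=self))

    def __rsub__(self, other):
        return Tensor._lift(other, like=self) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other, like=self)
        out_data = self.data * other.data

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other, like=self) * self ** -1.0

    def __pow__(self, exponent: float):
        p = float(exponent)
        out_data = self.data ** p

        def bw(g):
            return (g * p * self.data ** (p - 1.0),)

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            return (g @ other.data.T, self.data.T @ g)

        return Tensor._make(out_data, (self, other), bw)

    # -- shape & reductions ------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            return (g.reshape(orig),)

        return Tensor._make(out_data, (self,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                g = np.expand_dims(g, axes)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def gelu(x: Tensor) -> Tensor:
    """Gaussian-error linear unit, exact (erf) form."""
    x = Tensor._lift(x)
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out_data = x.data * phi

    def bw(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
        return (g * (phi + x.data * pdf),)

    return Tensor._make(out_data, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out_data = np.where(
        x.data >= 0,
        1.0 / (1.0 + np.exp(-np.abs(x.data))),
        np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))),
    )

    def bw(g):
        return (g * out_data * (1.0 - out_data),)

    return Tensor._make(out_data, (x,), bw)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix for same-size convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(col)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded 2-D convolution (cross-correlation convention).

    x: (N, C_in, H, W); weight: (C_out, C_in, k, k); bias: (C_out,).
    Output: (N, C_out, H, W).  Odd kernel sizes only.
    """
    x = Tensor._lift(x)
    weight = Tensor._lift(weight)
    n, c_in, h, w = x.data.shape
    c_out, c_in_w, k, k2 = weight.data.shape
    if c_in != c_in_w or k != k2 or k % 2 == 0:
        raise ValueError(
            f"conv2d: incompatible shapes x={x.data.shape} weight={weight.data.shape}"
        )
    pad = k // 2
    col = _im2col(x.data, k, pad)                       # (N*H*W, C_in*k*k)
    wmat = weight.data.reshape(c_out, c_in * k * k)     # (C_out, C_in*k*k)
    out = col @ wmat.T                                  # (N*H*W, C_out)
    if bias is not None:
        out = out + bias.data
    out_data = out.reshape(n, h, w, c_out).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, c_out)
        grad_w = grad_x = grad_b = None
        if weight.requires_grad:
            grad_w = (g2.T @ col).reshape(weight.data.shape)
        if bias is not None and bias.requires_grad:
            grad_b = g2.sum(axis=0)
        if x.requires_grad:
            dcol = (g2 @ wmat).reshape(n, h, w, c_in, k, k)
            dpad = np.zeros((n, c_in, h + 2 * pad, w + 2 * pad), dtype=g.dtype)
            dcol = dcol.transpose(0, 3, 1, 2, 4, 5)  # (N, C_in, H, W, k, k)
            for i in range(k):
                for j in range(k):
                    dpad[:, :, i : i + h, j : j + w] += dcol[:, :, :, :, i, j]
            grad_x = dpad[:, :, pad : pad + h, pad : pad + w]
        if bias is None:
            return (grad_x, grad_w)
        return (grad_x, grad_w, grad_b)

    return Tensor._make(out_data, parents, bw)


class Adam:
    """Adam optimizer with the standard moment defaults."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            m_hat = self.m[i] / b1t
            v_hat = self.v[i] / b2t
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
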
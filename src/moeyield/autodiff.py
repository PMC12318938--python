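"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations needed by the sequence-regression models in
this package: broadcasted arithmetic, (batched) matrix products, common
activations, softmax, reductions, concatenation, basic/advanced indexing and
row scatter.  Gradients are accumulated by topological-order backward sweeps.

The engine is CPU-only and deterministic; no operation uses threads or
platform-dependent reductions.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "concatenate",
    "relu",
    "gelu",
    "silu",
    "sigmoid",
    "tanh",
    "softmax",
    "scatter_rows",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (pure inference)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _is_basic_index(idx) -> bool:
    """True when `idx` contains only ints/slices (no duplicate targets)."""
    if isinstance(idx, tuple):
        return all(isinstance(i, (int, np.integer, slice)) or i is Ellipsis
                   for i in idx)
    return isinstance(idx, (int, np.integer, slice)) or idx is Ellipsis


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED:
            tracked = tuple(p for p in parents if p.requires_grad)
            if tracked:
                out.requires_grad = True
                out._parents = tracked
                out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        # promote 1-D operands through differentiable reshapes
        if self.data.ndim == 1 or other.data.ndim == 1:
            out_shape = np.matmul(self.data, other.data).shape
            lhs = self.reshape(1, -1) if self.data.ndim == 1 else self
            rhs = other.reshape(-1, 1) if other.data.ndim == 1 else other
            return (lhs @ rhs).reshape(*out_shape) if out_shape else \
                (lhs @ rhs).reshape(1)[0]
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(np.matmul(a, b), (self, other), backward)

    def __pow__(self, exponent: float) -> "Tensor":
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(self.data ** exponent, (self,), backward)

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        basic = _is_basic_index(idx)

        def backward(g):
            full = np.zeros_like(self.data)
            if basic:
                full[idx] = g
            else:
                np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows along axis 0 (gradient scatters back)."""
        return self[np.asarray(indices)]

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise functions ------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def abs(self) -> "Tensor":
        def backward(g):
            self._accum(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), backward)

    # -- autograd machinery ---------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode AD from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- free functions ---------------------------------------------------------

def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    parents = tuple(t for t in tensors if t.requires_grad)
    if parents:
        out.requires_grad = True
        out._parents = parents

        def backward(g):
            pieces = np.split(g, splits, axis=axis)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return x._make(np.where(mask, x.data, 0.0), (x,), backward)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) GELU."""
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data ** 2)
        x._accum(g * (cdf + x.data * pdf))

    return x._make(x.data * cdf, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * s * (1.0 - s))

    return x._make(s, (x,), backward)


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * (s + x.data * s * (1.0 - s)))

    return x._make(x.data * s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g):
        x._accum(g * (1.0 - t ** 2))

    return x._make(t, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return x._make(s, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis."""
    mu = x.data.mean(-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(-1, g.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(-1, keepdims=True)
            m2 = (dxhat * xhat).mean(-1, keepdims=True)
            x._accum(inv * (dxhat - m1 - xhat * m2))

    return x._make(out_data, (x, gamma, beta), backward)


def scatter_rows(values: Tensor, indices: np.ndarray, n_rows: int) -> Tensor:
    """Scatter-add `values` rows into a zero (n_rows, ...) tensor.

    Gradient gathers the corresponding rows back.
    """
    indices = np.asarray(indices)
    data = np.zeros((n_rows,) + values.data.shape[1:], dtype=np.float64)
    np.add.at(data, indices, values.data)

    def backward(g):
        values._accum(g[indices])

    return values._make(data, (values,), backward)
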
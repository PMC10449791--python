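"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Float64 tensors with a dynamically built computation graph; exactly the op
set the network needs (elementwise arithmetic, broadcast-aware, batched
matmul, relu/sigmoid/tanh, softmax, reductions, concat, row gather, clamp).
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    # -- graph walk ---------------------------------------------------------

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            # iterative DFS to avoid recursion limits on deep graphs
            stack: list[tuple[Tensor, bool]] = [(t, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- convenience --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- operators ----------------------------------------------------------

    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _wrap(-1.0)))

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitive ops -----------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def bw(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with NumPy batch broadcasting."""
    out_data = a.data @ b.data

    def bw(g: Array) -> None:
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2) if b.data.ndim > 1 else np.outer(g, b.data)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g if a.data.ndim > 1 else np.outer(a.data, g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bw(g: Array) -> None:
        a._accumulate(g * out_data)

    return Tensor(out_data, parents=(a,), backward=bw)


def log(a: Tensor) -> Tensor:
    def bw(g: Array) -> None:
        a._accumulate(g / a.data)

    return Tensor(np.log(a.data), parents=(a,), backward=bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g: Array) -> None:
        a._accumulate(g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=bw)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g: Array) -> None:
        a._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=bw)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bw(g: Array) -> None:
        a._accumulate(g * (1.0 - out_data**2))

    return Tensor(out_data, parents=(a,), backward=bw)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g: Array) -> None:
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate((g - dot) * out_data)

    return Tensor(out_data, parents=(a,), backward=bw)


def sum_(a: Tensor, axis: int | tuple[int, ...] | None = None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g: Array) -> None:
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward=bw)


def mean(a: Tensor, axis: int | None = None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), _wrap(1.0 / n))


def max_(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max reduction; gradient flows to the first argmax along the axis."""
    out_data = a.data.max(axis=axis, keepdims=keepdims)
    arg = np.expand_dims(a.data.argmax(axis=axis), axis)
    onehot = np.zeros_like(a.data)
    np.put_along_axis(onehot, arg, 1.0, axis=axis)

    def bw(g: Array) -> None:
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(onehot * g)

    return Tensor(out_data, parents=(a,), backward=bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def gather_rows(a: Tensor, indices: Array) -> Tensor:
    """Select rows (axis 0) by an integer index vector; duplicates allowed."""
    indices = np.asarray(indices, dtype=np.int64)
    out_data = a.data[indices]

    def bw(g: Array) -> None:
        ga = np.zeros_like(a.data)
        np.add.at(ga, indices, g)
        a._accumulate(ga)

    return Tensor(out_data, parents=(a,), backward=bw)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    def bw(g: Array) -> None:
        a._accumulate(g.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), parents=(a,), backward=bw)


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    def bw(g: Array) -> None:
        a._accumulate(np.swapaxes(g, ax1, ax2))

    return Tensor(np.swapaxes(a.data, ax1, ax2), parents=(a,), backward=bw)


def clamp(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; gradient is passed through only inside the bounds."""
    mask = (a.data > lo) & (a.data < hi)

    def bw(g: Array) -> None:
        a._accumulate(g * mask)

    return Tensor(np.clip(a.data, lo, hi), parents=(a,), backward=bw)
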
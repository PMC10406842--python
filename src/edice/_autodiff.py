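"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations required by the factorized attention model are
implemented: broadcast arithmetic, (batched) matmul, ReLU, softmax,
reductions, reshaping, gathering and concatenation.  Gradients are
accumulated in float64 or float32 depending on the input dtype.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_pairs", "relu", "softmax"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` over broadcast dimensions so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accumulate(_sum_to_shape(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(out.grad, other.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __sub__(self, other):
        return self + (self._wrap(other) * -1.0)

    def __rsub__(self, other):
        return self._wrap(other) + (self * -1.0)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accumulate(_sum_to_shape(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(out.grad * self.data, other.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_sum_to_shape(g, self.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accumulate(_sum_to_shape(g, other.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward():
            self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        out = self._make(out_data, (self,), backward)
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward():
            self._accumulate(out.grad.reshape(self.shape))

        out = self._make(out_data, (self,), backward)
        return out

    def transpose(self, *axes):
        out_data = self.data.transpose(*axes)
        inv = np.argsort(axes)

        def backward():
            self._accumulate(out.grad.transpose(*inv))

        out = self._make(out_data, (self,), backward)
        return out

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward():
        x._accumulate(out.grad * mask)

    out = x._make(out_data, (x,), backward)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward():
        g = out.grad
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    out = x._make(s, (x,), backward)
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out_data.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(idx)])

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(t for t in tensors if t.requires_grad)
        out._backward = backward
    return out


def gather_pairs(x: Tensor, batch_idx: np.ndarray, row_idx: np.ndarray) -> Tensor:
    """Select rows ``x[batch_idx[t], row_idx[t], :]`` -> [T, d]."""
    out_data = x.data[batch_idx, row_idx]

    def backward():
        g = np.zeros_like(x.data, dtype=out.grad.dtype)
        np.add.at(g, (batch_idx, row_idx), out.grad)
        x._accumulate(g)

    out = x._make(out_data, (x,), backward)
    return out
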
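"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operations the models in this package need:
broadcasting arithmetic, (batched) matrix products, reductions, elementwise
nonlinearities, indexing/gather, concatenation and reshaping.  Gradients are
accumulated by a topological backward sweep over the recorded graph.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float64


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd plumbing ----------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g)  # owned copy; later contributions add
        else:
            self.grad += g

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=DTYPE)
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)  # type: ignore[call-arg]
                node._backward = None
                node._parents = ()

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out: Tensor) -> None:
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(out: Tensor) -> None:
            a._accum(-out.grad)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out: Tensor) -> None:
            if a.requires_grad:
                a._accum(_unbroadcast(out.grad * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(out.grad * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        b = Tensor._coerce(other)
        return self * b ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def bw(out: Tensor) -> None:
            a._accum(out.grad * p * np.power(a.data, p - 1.0))

        return Tensor._make(np.power(a.data, p), (a,), bw)

    def __matmul__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(out: Tensor) -> None:
            g = out.grad
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(out: Tensor) -> None:
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        a = self
        val = np.exp(a.data)

        def bw(out: Tensor) -> None:
            a._accum(out.grad * val)

        return Tensor._make(val, (a,), bw)

    def log(self):
        a = self

        def bw(out: Tensor) -> None:
            a._accum(out.grad / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        val = np.sqrt(a.data)

        def bw(out: Tensor) -> None:
            a._accum(out.grad * 0.5 / val)

        return Tensor._make(val, (a,), bw)

    def tanh(self):
        a = self
        val = np.tanh(a.data)

        def bw(out: Tensor) -> None:
            a._accum(out.grad * (1.0 - val * val))

        return Tensor._make(val, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(out: Tensor) -> None:
            a._accum(out.grad * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        a = self
        c = np.sqrt(2.0 / np.pi)
        inner = c * (a.data + 0.044715 * a.data ** 3)
        t = np.tanh(inner)
        val = 0.5 * a.data * (1.0 + t)

        def bw(out: Tensor) -> None:
            d_inner = c * (1.0 + 3 * 0.044715 * a.data ** 2)
            grad = 0.5 * (1.0 + t) + 0.5 * a.data * (1.0 - t * t) * d_inner
            a._accum(out.grad * grad)

        return Tensor._make(val, (a,), bw)

    def sigmoid(self):
        a = self
        val = 1.0 / (1.0 + np.exp(-a.data))

        def bw(out: Tensor) -> None:
            a._accum(out.grad * val * (1.0 - val))

        return Tensor._make(val, (a,), bw)

    def clamp_max(self, hi: float):
        """Elementwise min(x, hi); gradient is zero where clipped."""
        a = self
        mask = a.data < hi

        def bw(out: Tensor) -> None:
            a._accum(out.grad * mask)

        return Tensor._make(np.minimum(a.data, hi), (a,), bw)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(out: Tensor) -> None:
            a._accum(out.grad.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def bw(out: Tensor) -> None:
            a._accum(np.swapaxes(out.grad, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(out: Tensor) -> None:
            g = np.zeros_like(a.data)
            np.add.at(g, idx, out.grad)
            a._accum(g)

        return Tensor._make(a.data[idx], (a,), bw)


# -- free functions ------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out: Tensor) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]

    def bw(out: Tensor) -> None:
        parts = np.moveaxis(out.grad, axis, 0)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t._accum(g)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tensors, bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtracting the (detached) max leaves the value and gradient unchanged
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def where_mask(mask: np.ndarray, x: Tensor, fill: float) -> Tensor:
    """x where mask is True, `fill` (constant, no gradient) elsewhere."""
    a = Tensor._coerce(x)
    m = np.asarray(mask, dtype=bool)

    def bw(out: Tensor) -> None:
        a._accum(out.grad * m)

    return Tensor._make(np.where(m, a.data, fill), (a,), bw)


def mean_pairwise_sq(a: Tensor, b: Tensor) -> Tensor:
    d = a - b
    return (d * d).mean()
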
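"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``np.ndarray`` and records the operations that
produced it; :meth:`Tensor.backward` walks the tape in reverse topological
order.  Only the operations the detection stack needs are implemented, and
each op's backward is written against the convention that gradients are
accumulated (``+=``) into ``.grad``.

Elementwise ops broadcast like numpy; their backwards un-broadcast by
summing over the expanded axes.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "no_grad", "concat", "stack", "where_max"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _grad_on(*tensors) -> bool:
    return _GRAD_ENABLED[-1] and any(
        isinstance(t, Tensor) and t.requires_grad for t in tensors)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


class Tensor:
    """An array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ---- plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float32)
        self.grad += g

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_on(*parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        # iterative topological sort (post-order)
        stack_ = [(self, iter(self._parents))]
        seen = {id(self)}
        while stack_:
            node, it = stack_[-1]
            advanced = False
            for p in it:
                if id(p) not in seen:
                    seen.add(id(p))
                    stack_.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack_.pop()

        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- elementwise arithmetic -------------------------------------

    def __add__(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = self.data + bd

        def bw(g):
            if isinstance(a, Tensor) and a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))
        return Tensor._make(out_data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(-g)
        return Tensor._make(-self.data, (a,), bw)

    def __sub__(self, other):
        return self + (-_ensure(other))

    def __rsub__(self, other):
        return _ensure(other) + (-self)

    def __mul__(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = self.data * bd

        def bw(g):
            if isinstance(a, Tensor) and a.requires_grad:
                a._accum(_unbroadcast(g * bd, a.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))
        return Tensor._make(out_data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = self.data / bd

        def bw(g):
            if isinstance(a, Tensor) and a.requires_grad:
                a._accum(_unbroadcast(g / bd, a.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (bd * bd), b.shape))
        return Tensor._make(out_data, (a, b), bw)

    def __rtruediv__(self, other):
        return _ensure(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self
        out_data = self.data ** p

        def bw(g):
            if a.requires_grad:
                a._accum(g * p * (a.data ** (p - 1)))
        return Tensor._make(out_data, (a,), bw)

    # ---- elementwise functions --------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(self.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * out_data)
        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self
        out_data = np.log(self.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g / a.data)
        return Tensor._make(out_data, (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(self.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * 0.5 / np.maximum(out_data, 1e-12))
        return Tensor._make(out_data, (a,), bw)

    def abs(self):
        a = self
        out_data = np.abs(self.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * np.sign(a.data))
        return Tensor._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))
        return Tensor._make(s, (a,), bw)

    def silu(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def bw(g):
            if a.requires_grad:
                a._accum(g * (s * (1.0 + a.data * (1.0 - s))))
        return Tensor._make(out_data, (a,), bw)

    def leaky_relu(self, slope: float = 0.1):
        a = self
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * np.where(mask, 1.0, slope).astype(np.float32))
        return Tensor._make(out_data, (a,), bw)

    def relu(self):
        return self.maximum(0.0)

    def maximum(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = np.maximum(self.data, bd)
        amask = (self.data >= bd).astype(np.float32)

        def bw(g):
            if isinstance(a, Tensor) and a.requires_grad:
                a._accum(_unbroadcast(g * amask, a.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                b._accum(_unbroadcast(g * (1.0 - amask), b.shape))
        return Tensor._make(out_data, (a, b), bw)

    def minimum(self, other):
        a, b = self, other
        bd = _as_array(b)
        out_data = np.minimum(self.data, bd)
        amask = (self.data <= bd).astype(np.float32)

        def bw(g):
            if isinstance(a, Tensor) and a.requires_grad:
                a._accum(_unbroadcast(g * amask, a.shape))
            if isinstance(b, Tensor) and b.requires_grad:
                b._accum(_unbroadcast(g * (1.0 - amask), b.shape))
        return Tensor._make(out_data, (a, b), bw)

    # ---- reductions -------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).astype(np.float32))
        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else (
            np.prod([self.shape[ax] for ax in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        a = self
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == expanded)
        # split ties evenly so the gradient stays well-defined
        counts = mask.sum(axis=axis, keepdims=True)
        w = mask / counts

        def bw(g):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum((w * gg).astype(np.float32))
        return Tensor._make(out_data, (a,), bw)

    # ---- shape ops --------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = self.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            if a.requires_grad:
                a._accum(g.reshape(old))
        return Tensor._make(out_data, (a,), bw)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))
        return Tensor._make(out_data, (a,), bw)

    def __getitem__(self, idx):
        a = self
        out_data = self.data[idx]

        def bw(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)
        return Tensor._make(out_data, (a,), bw)

    def pad2d(self, pad: int):
        """Zero-pad the two trailing axes by ``pad`` on each side."""
        if pad == 0:
            return self
        a = self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out_data = np.pad(self.data, width)
        sl = tuple([slice(None)] * (self.ndim - 2) +
                   [slice(pad, -pad), slice(pad, -pad)])

        def bw(g):
            if a.requires_grad:
                a._accum(g[sl])
        return Tensor._make(out_data, (a,), bw)

    def softmax(self, axis: int):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def matmul(self, other):
        a, b = self, _ensure(other)
        out_data = a.data @ b.data

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))
        return Tensor._make(out_data, (a, b), bw)

    __matmul__ = matmul


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list, axis: int) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors: list, axis: int) -> Tensor:
    tensors = [_ensure(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))
    return Tensor._make(out_data, tuple(tensors), bw)


def where_max(tensors: list) -> Tensor:
    """Elementwise maximum over a list (depth max-pool of the scale stack)."""
    out = tensors[0]
    for t in tensors[1:]:
        out = out.maximum(t)
    return out
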
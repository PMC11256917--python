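"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the compute engine for the model: a :class:`Tensor` wraps an
``ndarray``, records the operations applied to it, and :meth:`Tensor.backward`
accumulates gradients by reverse topological traversal.  Only the primitives
the model needs are implemented (broadcasting arithmetic, batched matmul,
reductions, gather/concat/reshape, elementwise nonlinearities).  Everything is
deterministic: no op consumes randomness.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                 dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order
        visiting: list[tuple[Tensor, int]] = [(self, 0)]
        while visiting:
            node, state = visiting.pop()
            if state == 0:
                if id(node) in seen:
                    continue
                seen.add(id(node))
                visiting.append((node, 1))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        visiting.append((p, 0))
            else:
                topo.append(node)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(
                        -g * self.data / (other.data ** 2), other.data.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(
                g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data),
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accum(_unbroadcast(ga, self.data.shape))
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accum(_unbroadcast(gb, other.data.shape))
            out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ----------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g * (1.0 - val ** 2))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(val, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mult = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mult, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g * mult)
        return out

    # ------------------------------------------------------------- structure
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    def take_rows(self, index: np.ndarray, axis: int = -2):
        """Batched row gather: index has the batch shape of self minus the
        gathered axis; e.g. self (B,T,D), index (B,K) -> (B,K,D)."""
        if self.ndim == 2 and axis == -2:
            return self[np.asarray(index)]
        if self.ndim == 3 and axis == -2:
            b = np.arange(self.shape[0])[:, None]
            return self[b, np.asarray(index)]
        raise NotImplementedError("take_rows supports 2D/3D, axis=-2")

    # ------------------------------------------------------------ composites
    def softmax(self, axis: int = -1):
        # fused primitive: this is the hottest op in the model
        m = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(m, out=m)
        m /= m.sum(axis=axis, keepdims=True)
        out = Tensor(m, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bw(g):
                tmp = g * m
                self._accum(tmp - m * tmp.sum(axis=axis, keepdims=True))
            out._backward = bw
        return out

    def log_softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bw
    return out


def stack(tensors: list, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)

        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = bw
    return out
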
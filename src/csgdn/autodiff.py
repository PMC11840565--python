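"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray, records the operations that
produced it, and accumulates gradients through :meth:`Tensor.backward`.
The op set is exactly what the graph encoder and loss functions need:
broadcasting arithmetic, matmul, exp/log/sqrt/power, reductions, piecewise
activations, concatenation, and integer-array row gathering.  Everything
runs in float64, which keeps finite-difference gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "leaky_relu", "relu", "elu"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the reverse-mode computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_ng")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward
        # whether any gradient can flow to or through this node; ops consult
        # it to skip computing gradient contributions for constants
        self._ng = self.requires_grad or any(p._ng for p in parents)

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Accumulate gradients of this (scalar by default) tensor's parents."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order over the dynamic graph
        topo, seen = [], set()
        stack = [(self, False)]
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
                if p._ng and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, contrib in node._backward(node.grad):
                if parent._ng:
                    add = _unbroadcast(np.asarray(contrib), parent.data.shape)
                    parent.grad = add if parent.grad is None else parent.grad + add

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            backward=lambda g: ((self, g), (other, g)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: ((self, -g),))

    def __sub__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data - other.data,
            parents=(self, other),
            backward=lambda g: ((self, g), (other, -g)),
        )

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        other = self._lift(other)

        def back(g):
            out = []
            if self._ng:
                out.append((self, g * other.data))
            if other._ng:
                out.append((other, g * self.data))
            return out

        return Tensor(self.data * other.data, parents=(self, other), backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def back(g):
            out = []
            if self._ng:
                out.append((self, g / other.data))
            if other._ng:
                out.append((other, -g * self.data / other.data**2))
            return out

        return Tensor(self.data / other.data, parents=(self, other), backward=back)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = self.data**exponent
        return Tensor(
            out,
            parents=(self,),
            backward=lambda g: ((self, g * exponent * self.data ** (exponent - 1)),),
        )

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def back(g):
            g = np.asarray(g)
            out = []
            if self._ng:
                if a.ndim == 1 and b.ndim == 1:
                    out.append((self, g * b))  # inner product -> scalar
                elif a.ndim == 2 and b.ndim == 1:
                    out.append((self, np.outer(g, b)))  # (n,m)@(m,) -> (n,)
                else:
                    out.append((self, g @ b.T))
            if other._ng:
                if b.ndim == 1 and a.ndim == 1:
                    out.append((other, g * a))
                elif a.ndim == 1 and b.ndim == 2:
                    out.append((other, np.outer(a, g)))  # (n,)@(n,m) -> (m,)
                else:
                    out.append((other, a.T @ g))
            return out

        return Tensor(a @ b, parents=(self, other), backward=back)

    # -------------------------------------------------------------- elementwise
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), backward=lambda g: ((self, g * out),))

    def log(self, floor: float = 0.0):
        """Natural log; with ``floor`` > 0 the argument is clamped below."""
        arg = np.maximum(self.data, floor) if floor > 0 else self.data
        out = np.log(arg)

        def back(g):
            grad = g / arg
            if floor > 0:
                grad = np.where(self.data > floor, grad, 0.0)
            return ((self, grad),)

        return Tensor(out, parents=(self,), backward=back)

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(
            out, parents=(self,), backward=lambda g: ((self, g / (2.0 * out)),)
        )

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(
            out, parents=(self,), backward=lambda g: ((self, g * (1 - out**2)),)
        )

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        return Tensor(out, parents=(self,), backward=back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape & index
    @property
    def T(self):
        return Tensor(
            self.data.T, parents=(self,), backward=lambda g: ((self, g.T),)
        )

    def reshape(self, *shape):
        return Tensor(
            self.data.reshape(*shape),
            parents=(self,),
            backward=lambda g: ((self, g.reshape(self.data.shape)),),
        )

    def take_rows(self, index):
        """Gather rows by an integer index array (axis 0)."""
        index = np.asarray(index, dtype=int)

        def back(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, index, g)
            return ((self, grad),)

        return Tensor(self.data[index], parents=(self,), backward=back)


def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, parts))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=back,
    )


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(
        x.data * mask, parents=(x,), backward=lambda g: ((x, g * mask),)
    )


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mult = np.where(x.data > 0, 1.0, slope)
    return Tensor(
        x.data * mult, parents=(x,), backward=lambda g: ((x, g * mult),)
    )


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    expm1 = alpha * np.expm1(np.minimum(x.data, 0.0))
    out = np.where(pos, x.data, expm1)
    mult = np.where(pos, 1.0, expm1 + alpha)
    return Tensor(out, parents=(x,), backward=lambda g: ((x, g * mult),))
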
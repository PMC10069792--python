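"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small (tens of thousands of parameters)
and train on at most a few hundred samples, so a compact tape-based
autodiff engine is sufficient and keeps the whole model stack dependency
free.  Tensors wrap ``numpy.ndarray`` values; operations record a local
backward closure and ``backward()`` walks the tape in reverse topological
order accumulating gradients.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape (``_unbroadcast``).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # Sum over leading dimensions added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Sum over axes that were broadcast from size 1.
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with gradient tracking."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def param(value) -> "Tensor":
        return Tensor(value, requires_grad=True)

    @staticmethod
    def const(value) -> "Tensor":
        return Tensor(value, requires_grad=False)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.value.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor.const(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, True, (self, other))
        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(g)
            if other.requires_grad or other._parents:
                other._accumulate(g)
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, True, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, True, (self, other))
        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(g * other.value)
            if other.requires_grad or other._parents:
                other._accumulate(g * self.value)
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.value / other.value, True, (self, other))
        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(g / other.value)
            if other.requires_grad or other._parents:
                other._accumulate(-g * self.value / other.value ** 2)
        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.value ** exponent, True, (self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.value ** (exponent - 1)
        )
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        """Matrix product; supports batched (...,m,k) @ (k,n) and (...,m,k) @ (...,k,n)."""
        other = self._lift(other)
        out = Tensor(self.value @ other.value, True, (self, other))
        def backward(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ np.swapaxes(other.value, -1, -2))
            if other.requires_grad or other._parents:
                other._accumulate(np.swapaxes(self.value, -1, -2) @ g)
        out._backward = backward
        return out

    __matmul__ = matmul

    # -- elementwise nonlinearities ------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.value > 0
        out = Tensor(self.value * mask, True, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.value)
        out = Tensor(val, True, (self,))
        out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.value), True, (self,))
        out._backward = lambda g: self._accumulate(g / self.value)
        return out

    # -- reductions and shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), True, (self,))
        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.value.shape))
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.value.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.value.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape) -> "Tensor":
        orig = self.value.shape
        out = Tensor(self.value.reshape(*shape), True, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose_last(self) -> "Tensor":
        """Swap the last two axes."""
        out = Tensor(np.swapaxes(self.value, -1, -2), True, (self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, -1, -2))
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.value - self.value.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, True, (self,))
        def backward(g):
            # d softmax: s * (g - sum(g*s))
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))
        out._backward = backward
        return out


def concatenate(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    values = [t.value for t in tensors]
    out = Tensor(np.concatenate(values, axis=axis), True, tuple(tensors))
    sizes = [v.shape[axis] for v in values]
    splits = np.cumsum(sizes)[:-1]
    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)
    out._backward = backward
    return out


class Adam:
    """Adaptive-moment gradient optimizer (the paper-standard choice)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Glorot/Xavier fan-based uniform initialisation."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)
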
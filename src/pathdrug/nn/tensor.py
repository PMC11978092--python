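"""A small vectorized reverse-mode automatic-differentiation engine.

The model in :mod:`pathdrug.model` is built on this numpy ``Tensor``: each
operation records its inputs and a backward closure; :meth:`Tensor.backward`
runs the reverse topological sweep and accumulates gradients into
``requires_grad`` leaves. Broadcasting follows numpy semantics, with
gradients summed back over broadcast dimensions.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
        _backward: Callable[[Array], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=float)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev
        self._backward = _backward

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Array | None = None) -> None:
        """Reverse sweep from this tensor, filling leaf ``.grad`` fields."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._prev))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen and child.requires_grad:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None  # free intermediate grads; leaves keep theirs

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _prev=(self,))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward(g: Array) -> None:
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:  # dot product
                if self.requires_grad:
                    self._accumulate(g * b)
                if other.requires_grad:
                    other._accumulate(g * a)
                return
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.expand_dims(g, -1) * b  # outer product rows
                elif a.ndim == 1:
                    ga = g @ np.swapaxes(b, -1, -2)
                    ga = _unbroadcast(ga, a.shape)
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                    ga = _unbroadcast(ga, a.shape)
                self._accumulate(ga)
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
                    gb = _unbroadcast(gb, b.shape)
                elif b.ndim == 1:
                    gb = np.swapaxes(a, -1, -2) @ np.expand_dims(g, -1)
                    gb = _unbroadcast(gb.squeeze(-1), b.shape)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                    gb = _unbroadcast(gb, b.shape)
                other._accumulate(gb)

        out._backward = backward
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))
        # capture the array, not `out`: a closure referencing its own tensor
        # would form a reference cycle that delays freeing large buffers
        out._backward = lambda g: self.requires_grad and self._accumulate(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (1.0 - t**2)
        )
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (self.data > 0)
        )
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * s * (1.0 - s)
        )
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax along ``axis``."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def backward(g: Array) -> None:
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accumulate(s * (g - dot))

        out._backward = backward
        return out

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.shape)
        )
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(self.data.swapaxes(a, b), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.swapaxes(a, b)
        )
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _prev=(self,))

        def backward(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        out._backward = backward
        return out

    def take_rows(self, indices: Array) -> "Tensor":
        """Row lookup ``self[indices]`` for embedding tables."""
        idx = np.asarray(indices)
        out = Tensor(self.data[idx], _prev=(self,))

        def backward(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx.reshape(-1), g.reshape(-1, self.data.shape[-1]))
                self._accumulate(full)

        out._backward = backward
        return out


def concatenate(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def backward(g: Array) -> None:
        parts = np.split(g, len(tensors), axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(part.squeeze(axis))

    out._backward = backward
    return out
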
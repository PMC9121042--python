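"""Reverse-mode autodiff core: a Tensor wrapping an ndarray plus a tape.

Each op returns a new :class:`Tensor` holding references to its parents and a
closure that maps the output gradient to parent gradients.  ``Tensor.backward``
runs a topological sweep and accumulates ``.grad`` on every tensor that
requires gradients.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)

    # -- introspection ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph execution ----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs would overflow recursion
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
        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                pg = _unbroadcast(pg, parent.data.shape)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            _parents=(self, other),
            _backward=lambda g: (g, g),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(self, other),
            _backward=lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(self, other),
            _backward=lambda g: (g / other.data, -g * self.data / other.data**2),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def back(g):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return ga, gb

        return Tensor(np.matmul(a, b), _parents=(self, other), _backward=back)

    def __pow__(self, p: float):
        return Tensor(
            self.data**p,
            _parents=(self,),
            _backward=lambda g: (g * p * self.data ** (p - 1),),
        )

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.data.shape).copy(),)

        return Tensor(out, _parents=(self,), _backward=back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _backward=lambda g: (g.reshape(old),),
        )

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            _parents=(self,),
            _backward=lambda g: (g.transpose(inv),),
        )

    def __getitem__(self, key):
        def back(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return (out,)

        return Tensor(self.data[key], _parents=(self,), _backward=back)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, _parents=(x,), _backward=lambda g: (g * mask,))


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)
    return Tensor(out, _parents=(x,), _backward=lambda g: (g * out,))


def sqrt(x: Tensor) -> Tensor:
    out = np.sqrt(x.data)
    return Tensor(out, _parents=(x,), _backward=lambda g: (g * 0.5 / out,))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    return Tensor(s, _parents=(x,), _backward=back)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = shifted - lse

    def back(g):
        return (g - np.exp(out) * g.sum(axis=axis, keepdims=True),)

    return Tensor(out, _parents=(x,), _backward=back)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=back,
    )
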
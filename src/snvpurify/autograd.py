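"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine exists to train the correction network; it supports exactly the
operations that network needs (affine maps, batched matmul for attention,
pointwise nonlinearities, reductions, reshapes) in float64, which keeps
training bitwise reproducible under a fixed seed and makes finite-difference
gradient checks tight.

A :class:`Tensor` wraps an ``ndarray`` and records the backward closure of
the op that produced it; :meth:`Tensor.backward` runs a topological sweep.
Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "softmax", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (many blocks/epochs)
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
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(p for p in parents)
        needs = any(p.requires_grad or p._parents for p in parents)
        if not needs:
            return Tensor(data)
        return Tensor(data, parents=parents, backward=backward)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data / other.data

        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data ** 2))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._wrap(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accumulate(g * b)
                other._accumulate(g * a)
                return
            ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
            gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- pointwise nonlinearities --------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bw(g):
            self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), bw)

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def bw(g):
            self._accumulate(g * (self.data > 0.0))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def softplus(self) -> "Tensor":
        # numerically stable: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * sig)

        return Tensor._make(out_data, (self,), bw)

    def abs(self) -> "Tensor":
        def bw(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bw)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accumulate(np.reshape(g, old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), bw)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def bw(g):
            self._accumulate(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` (max-shifted for stability; the shift is a
    constant with respect to the gradient)."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / ((var + eps) ** 0.5) * gain + bias
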
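"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the sequence classifiers need: broadcasted
arithmetic, (batched) matrix multiplication, elementwise nonlinearities,
reductions, reshapes, padding/slicing along the time axis, and fused
softmax / log-softmax / layer-norm primitives with analytic gradients.
Gradients flow through a dynamically built graph; ``backward`` runs a
topological sweep from a scalar loss.

All data is float64; the engine is single-threaded and fully deterministic.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph: value, gradient and backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers ------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def slice_axis(self, axis: int, start: int, stop: int):
        index = [slice(None)] * self.data.ndim
        index[axis] = slice(start, stop)
        index = tuple(index)
        out_data = self.data[index]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[index] = g
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def pad_axis(self, axis: int, before: int, after: int):
        pad = [(0, 0)] * self.data.ndim
        pad[axis] = (before, after)
        out_data = np.pad(self.data, pad)
        index = [slice(None)] * self.data.ndim
        index[axis] = slice(before, before + self.data.shape[axis])
        index = tuple(index)

        def backward(g):
            if self.requires_grad:
                self._accum(g[index])

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- backward ------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() must start from a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._parents))]
        seen.add(id(self))
        while stack:
            node, it = stack[-1]
            advanced = False
            for parent in it:
                if id(parent) not in seen and parent.requires_grad:
                    seen.add(id(parent))
                    stack.append((parent, iter(parent._parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------------------
# elementwise nonlinearities


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0

    def backward(g):
        if t.requires_grad:
            t._accum(g * mask)

    return Tensor._make(t.data * mask, (t,), backward)


def exp(t: Tensor) -> Tensor:
    out_data = np.exp(t.data)

    def backward(g):
        if t.requires_grad:
            t._accum(g * out_data)

    return Tensor._make(out_data, (t,), backward)


def tanh(t: Tensor) -> Tensor:
    out_data = np.tanh(t.data)

    def backward(g):
        if t.requires_grad:
            t._accum(g * (1.0 - out_data ** 2))

    return Tensor._make(out_data, (t,), backward)


def sigmoid(t: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-t.data))

    def backward(g):
        if t.requires_grad:
            t._accum(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (t,), backward)


# ---------------------------------------------------------------------------
# fused primitives


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if t.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            t._accum(out_data * (g - dot))

    return Tensor._make(out_data, (t,), backward)


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t.data - t.data.max(axis=axis, keepdims=True)
    logsum = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - logsum
    sm = np.exp(out_data)

    def backward(g):
        if t.requires_grad:
            t._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return Tensor._make(out_data, (t,), backward)


def layer_norm(t: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = t.data.mean(axis=-1, keepdims=True)
    var = t.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (t.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if t.requires_grad:
            dxhat = g * gamma.data
            m = dxhat.mean(axis=-1, keepdims=True)
            mx = (dxhat * xhat).mean(axis=-1, keepdims=True)
            t._accum(inv * (dxhat - m - xhat * mx))

    return Tensor._make(out_data, (t, gamma, beta), backward)


def dropout(t: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not training or rate <= 0.0:
        return t
    mask = (rng.random(t.data.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)
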
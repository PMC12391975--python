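"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs: broadcast arithmetic,
(batched) matmul, elementwise nonlinearities, axis reductions including max,
row gathering, concatenation, reshape/transpose and a softmax primitive.
Gradients are accumulated by topological-order backpropagation from a scalar
loss. Tensors wrap float64 arrays; anything passed to an op that is not a
Tensor is treated as a constant.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
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

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this scalar."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = self._node(self.data + other.data, (self, other), None)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._node(-self.data, (self,), None)
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._node(self.data * other.data, (self, other), None)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._node(self.data / other.data, (self, other), None)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._node(self.data @ other.data, (self, other), None)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif a.ndim == 1:  # (k,) @ (..., k, m) -> (..., m)
                ga = (g[..., None, :] @ np.swapaxes(b, -1, -2)).reshape(-1, a.shape[0]).sum(0)
                gb = a[:, None] @ g[..., None, :]
            elif b.ndim == 1:  # (..., n, k) @ (k,) -> (..., n)
                ga = g[..., None] * b
                gb = (np.swapaxes(a, -1, -2) @ g[..., None])[..., 0]
                while gb.ndim > 1:
                    gb = gb.sum(axis=0)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = self._node(self.data**exponent, (self,), None)
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = self._node(y, (self,), None)
        out._backward = lambda g: self._accum(g * (1 - y**2))
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = self._node(y, (self,), None)
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = self._node(y, (self,), None)
        out._backward = lambda g: self._accum(g * y * (1 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = self._node(y, (self,), None)
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = self._node(np.log(self.data), (self,), None)
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = self._node(y, (self,), None)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accum(y * (g - dot))

        out._backward = backward
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max reduction; gradient routes to the (first) argmax entries."""
        y = self.data.max(axis=axis, keepdims=True)
        mask = self.data == y
        # route to a single argmax per slice for a well-defined subgradient
        first = np.cumsum(mask, axis=axis) == 1
        mask = mask & first
        out_data = y if keepdims else np.squeeze(y, axis=axis)
        out = self._node(out_data, (self,), None)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * g)

        out._backward = backward
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        out = self._node(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = self._node(np.swapaxes(self.data, a, b), (self,), None)
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._node(data, tuple(tensors), None)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out._backward = backward
    return out


def gather_rows(x: Tensor, indices: np.ndarray) -> Tensor:
    """Select rows of a 2-D tensor; backward scatter-adds into the source."""
    indices = np.asarray(indices, dtype=np.int64)
    out = Tensor._node(x.data[indices], (x,), None)

    def backward(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, indices, g)
        x._accum(acc)

    out._backward = backward
    return out
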
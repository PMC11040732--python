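"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the ALDELE networks need: dense and
convolutional algebra (matmul, add, mul, slicing, concatenation), the
nonlinearities (ReLU, sigmoid, exp/log for softmax and cross-entropy),
reductions (sum, mean, max) and integer-array indexing for embedding
lookups.  Gradients are accumulated by a topological-order sweep over the
recorded computation graph, with broadcasting handled by summing gradients
back to the parent shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "relu", "sigmoid", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # ---- basic properties -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- graph machinery --------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                a = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(a, self.data.shape))
            if other.requires_grad:
                b = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(b, other.data.shape))

        out._backward = bwd
        return out

    # ---- shaping ----------------------------------------------------------
    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.T)

        out._backward = bwd
        return out

    # ---- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                mask = (self.data == out_data).astype(np.float64)
                mask /= mask.sum()
                self._accumulate(mask * g)
            else:
                full = self.data.max(axis=axis, keepdims=True)
                mask = (self.data == full).astype(np.float64)
                mask /= mask.sum(axis=axis, keepdims=True)
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(mask * gg)

        out._backward = bwd
        return out

    # ---- elementwise nonlinearities ---------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        out._backward = bwd
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = bwd
        return out

    def exp(self):
        e = np.exp(np.clip(self.data, -700, 700))
        out = Tensor(e, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def relu(t: Tensor) -> Tensor:
    return t.relu()


def sigmoid(t: Tensor) -> Tensor:
    return t.sigmoid()


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    # shift by a constant for stability; the constant has zero gradient effect
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a flat list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
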
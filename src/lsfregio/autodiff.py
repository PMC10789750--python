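"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the message-passing network and its losses
need: broadcast add/mul, matmul, elementwise nonlinearities, reductions and
concatenation. Gradients are accumulated by a topological backward sweep.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers ------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accum(g)
            other._accum(g)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __matmul__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------

    def log(self):
        def backward(g):
            self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            self._accum(g * out_data)
        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))
        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))
        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g):
            self._accum(g * mask)
        return self._make(self.data * mask, (self,), backward)

    def clamp(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        def backward(g):
            self._accum(g * mask)
        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- shape ops ------------------------------------------------------

    def sum(self):
        def backward(g):
            self._accum(np.broadcast_to(g, self.data.shape))
        return self._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size
        def backward(g):
            self._accum(np.broadcast_to(g / n, self.data.shape))
        return self._make(self.data.mean(), (self,), backward)

    def rows(self, index: np.ndarray):
        """Select rows by integer index array."""
        index = np.asarray(index)
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            self._accum(full)
        return self._make(self.data[index], (self,), backward)

    # -- backward sweep --------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis."""
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a flat list of parameter tensors.

    ``clip_norm`` rescales the global gradient norm before each step,
    which keeps the loss finite when weighting schemes spike.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _clip(self) -> None:
        if self.clip_norm is None:
            return
        total = np.sqrt(sum(float(np.sum(p.grad ** 2))
                            for p in self.params if p.grad is not None))
        if total > self.clip_norm:
            scale = self.clip_norm / total
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self) -> None:
        self._clip()
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
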
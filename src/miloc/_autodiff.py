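"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph attention auto-encoder and the
self-attention classifier need: (batched) matmul, broadcasting add/mul,
element-wise nonlinearities, masked softmax, reductions, reshape/transpose
and concatenation.  Gradients are accumulated by topological-order backward
passes; an Adam optimizer updates parameter tensors in place.
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def matmul(self, other):
        """Matrix product; supports stacked (batched) operands."""
        a, b = self, Tensor._lift(other)

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                if b.data.ndim == 2 and g.ndim > 2:
                    # broadcasted 2-D weight against stacked operand: collapse
                    # the batch instead of materializing per-item gradients
                    gb = a.data.reshape(-1, a.data.shape[-1]).T @ \
                        g.reshape(-1, g.shape[-1])
                    b._accumulate(gb)
                else:
                    gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                    b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    __matmul__ = matmul

    # -- element-wise ------------------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * (1 - out_data**2))

        return Tensor._make(out_data, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only where not clamped."""
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; identity when rate is 0."""
        if rate <= 0:
            return self
        a = self
        keep = (rng.random(a.shape) >= rate) / (1.0 - rate)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * keep)

        return Tensor._make(a.data * keep, (a,), backward)

    def take_rows(self, indices: np.ndarray):
        """Row gather ``out[k] = self[indices[k]]`` with scatter-add backward."""
        a = self
        idx = np.asarray(indices, dtype=np.intp)

        def backward(g):
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                np.add.at(acc, idx, g)
                a._accumulate(acc)

        return Tensor._make(a.data[idx], (a,), backward)

    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        parts = tuple(tensors)
        sizes = [t.data.shape[axis] for t in parts]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, piece in zip(parts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        return Tensor._make(
            np.concatenate([t.data for t in parts], axis=axis), parts, backward
        )

    @staticmethod
    def stack(tensors: list["Tensor"], axis: int) -> "Tensor":
        parts = tuple(tensors)

        def backward(g):
            for k, t in enumerate(parts):
                if t.requires_grad:
                    t._accumulate(np.take(g, k, axis=axis))

        return Tensor._make(
            np.stack([t.data for t in parts], axis=axis), parts, backward
        )

    def masked_softmax(self, mask: np.ndarray, axis: int = -1):
        """Softmax along ``axis`` restricted to positions where mask > 0.

        Rows with an all-zero mask produce all-zero output.
        """
        a = self
        m = np.asarray(mask, dtype=bool)
        shifted = np.where(m, a.data, -np.inf)
        shifted = shifted - shifted.max(axis=axis, keepdims=True, initial=-1e30)
        e = np.where(m, np.exp(shifted), 0.0)
        denom = e.sum(axis=axis, keepdims=True)
        out_data = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)

        def backward(g):
            if a.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                a._accumulate(out_data * (g - dot))

        return Tensor._make(out_data, (a,), backward)

    def softmax(self, axis: int = -1):
        return self.masked_softmax(np.ones_like(self.data, dtype=bool), axis=axis)


class Adam:
    """Adam optimizer with optional decoupled weight decay (AdamW)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                p.data *= 1 - self.lr * self.weight_decay


def glorot(rng: np.random.Generator, *shape: int) -> Tensor:
    """Glorot-uniform initialized parameter tensor."""
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[-1], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)
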
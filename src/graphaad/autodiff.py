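"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the EEG graph classifier needs: broadcasted
arithmetic, (batched) matrix products, reductions, indexing/gather,
segment-sum scatter, softmax, leaky ReLU and a fused softmax cross-entropy.
Everything is float64; gradients are accumulated by topological traversal of
the recorded operation graph.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "segment_sum", "softmax", "leaky_relu",
           "cross_entropy", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

    # -- basic arithmetic --------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(a.data ** p, (a,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                if b.data.ndim == 1:
                    ga = np.multiply.outer(g, b.data) if g.ndim else g * b.data
                else:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                if a.data.ndim == 1:
                    gb = np.multiply.outer(a.data, g)
                else:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g.swapaxes(ax1, ax2))

        return Tensor._make(a.data.swapaxes(ax1, ax2), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                ga = np.zeros_like(a.data)
                np.add.at(ga, idx, g)
                a._accum(ga)

        return Tensor._make(a.data[idx], (a,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if a.requires_grad:
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    @property
    def shape(self):
        return self.data.shape


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    """Piecewise-linear activation: x for x >= 0, slope * x otherwise."""
    x = Tensor._coerce(x)
    mask = np.where(x.data >= 0, 1.0, negative_slope)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilized softmax along `axis`."""
    x = Tensor._coerce(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            inner = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - inner))

    return Tensor._make(s, (x,), backward)


def segment_sum(x: Tensor, index: np.ndarray, n_segments: int) -> Tensor:
    """Scatter-add rows of `x` into `n_segments` bins given by `index`."""
    x = Tensor._coerce(x)
    index = np.asarray(index, dtype=np.intp)
    out_data = np.zeros((n_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, index, x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g[index])

    return Tensor._make(out_data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of class logits."""
    logits = Tensor._coerce(logits)
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = labels.shape[0]
    loss = -log_probs[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            probs = np.exp(log_probs)
            probs[np.arange(n), labels] -= 1.0
            logits._accum(g * probs / n)

    return Tensor._make(loss, (logits,), backward)


class Adam:
    """Adam optimizer with the canonical published constants."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
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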
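"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module is the numerical core behind the bimodal attention network: a
small tensor type recording a computation graph, the handful of primitives
the architecture needs (broadcast-aware add/mul, batched matmul, tanh, ReLU,
softmax, 1-D unfold for convolutions, embedding row gather, dropout, a
numerically stable binary cross-entropy on logits) and an Adam optimizer.

Gradients flow through a topological sweep of the recorded graph; every
primitive defines its own vector-Jacobian product. Arrays are float64
throughout — at the desk scales this package targets, reproducibility and
simplicity beat single-precision speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "unfold1d", "take_rows", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph.

    Parameters are Tensors with ``requires_grad=True``; constants and inputs
    are plain leaves. ``trainable`` is an optimizer-level switch used to
    freeze parameter subsets without touching graph construction.
    """

    __slots__ = ("data", "grad", "requires_grad", "trainable", "name",
                 "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self.trainable = requires_grad
        self.name = name
        self._parents: tuple = ()
        self._backward = None

    # -- graph bookkeeping -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._from_op(out_data, (self,), backward)

    def dropout(self, p: float, rng: np.random.Generator):
        """Inverted dropout; call only in training mode."""
        if p <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def unfold1d(x: Tensor, kernel: int) -> Tensor:
    """Extract sliding windows for a same-padded 1-D convolution.

    Input (B, L, C) -> output (B, L, kernel*C); window i covers positions
    i - k//2 .. i + (k-1)//2 with zero padding outside the sequence, so a
    following matmul with a (kernel*C, F) weight is a stride-1 convolution
    that preserves L.
    """
    B, L, C = x.data.shape
    left = (kernel - 1) // 2
    padded = np.zeros((B, L + kernel - 1, C))
    padded[:, left:left + L, :] = x.data
    windows = np.stack([padded[:, i:i + L, :] for i in range(kernel)], axis=2)
    out_data = windows.reshape(B, L, kernel * C)

    def backward(g):
        if not x.requires_grad:
            return
        gw = g.reshape(B, L, kernel, C)
        gpad = np.zeros((B, L + kernel - 1, C))
        for i in range(kernel):
            gpad[:, i:i + L, :] += gw[:, :, i, :]
        x._accumulate(gpad[:, left:left + L, :])

    return Tensor._from_op(out_data, (x,), backward)


def take_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup: gather rows of `table` (V, D) by integer `idx` (...,)."""
    idx = np.asarray(idx)
    out_data = table.data[idx]

    def backward(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, idx.reshape(-1), g.reshape(-1, table.data.shape[1]))
            table._accumulate(gt)

    return Tensor._from_op(out_data, (table,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
    # log(1 + exp(z)) - y*z, computed stably
    loss = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    out_data = np.array(loss.mean())
    n = z.size

    def backward(g):
        if logits.requires_grad:
            p = 0.5 * (1.0 + np.tanh(0.5 * z))
            logits._accumulate(g * (p - y) / n)

    return Tensor._from_op(out_data, (logits,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors.

    Skips parameters whose ``trainable`` flag is off, leaving their values
    bit-identical — the mechanism behind semifrozen fine-tuning.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = {id(p): np.zeros_like(p.data) for p in self.params}
        self._v = {id(p): np.zeros_like(p.data) for p in self.params}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            if not p.trainable or p.grad is None:
                continue
            m = self._m[id(p)]
            v = self._v[id(p)]
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
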
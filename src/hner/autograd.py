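"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
:meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  The op set is exactly what the sequence tagger
needs — broadcasting arithmetic, matmul, pointwise nonlinearities, reductions
(sum / max / logsumexp), indexing and concatenation — and every op's gradient
is covered by finite-difference tests.  float64 throughout: model sizes here
are small and gradient checks want the precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- helpers ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _acc(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._acc(_unbroadcast(g, a.data.shape))
            b._acc(_unbroadcast(g, b.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._acc(_unbroadcast(g * b.data, a.data.shape))
            b._acc(_unbroadcast(g * a.data, b.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g, a=self):
            a._acc(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            a._acc(_unbroadcast(g / b.data, a.data.shape))
            b._acc(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            if a.data.ndim == 1:  # vector @ matrix
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._acc(_unbroadcast(ga, a.data.shape))
            b._acc(_unbroadcast(gb, b.data.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, o=out_data):
            a._acc(g * (1.0 - o ** 2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g, a=self, o=out_data):
            a._acc(g * o * (1.0 - o))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            a._acc(g * m)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            a._acc(g * o)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._acc(g / a.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._acc(np.broadcast_to(g, a.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the (first) argmax."""
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims, o=out_data):
            if not kd:
                g = np.expand_dims(g, ax)
                o = np.expand_dims(o, ax)
            mask = a.data == o
            # split gradient over ties so the check against finite
            # differences stays bounded; ties are measure-zero in training
            mask = mask / mask.sum(axis=ax, keepdims=True)
            a._acc(g * mask)

        return self._make(out_data, (self,), backward)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = np.log(s) + m
        soft = e / s
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g, a=self, ax=axis, kd=keepdims, p=soft):
            if not kd:
                g = np.expand_dims(g, ax)
            a._acc(g * p)

        return self._make(out_data, (self,), backward)

    # -- shape / indexing ---------------------------------------------------

    def reshape(self, *shape):
        def backward(g, a=self):
            a._acc(g.reshape(a.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g, a=self, iv=inv):
            a._acc(g.transpose(iv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, ix=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, ix, g)
            a._acc(full)

        return self._make(self.data[idx], (self,), backward)

    # -- graph traversal -----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: sequence graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._acc(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis (differentiable)."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(g, ts=tuple(tensors), offs=offsets, ax=axis):
            for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._acc(g[tuple(sl)])

        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis (differentiable)."""
    datas = [t.data for t in tensors]
    out = Tensor(np.stack(datas, axis=axis))
    if any(t.requires_grad for t in tensors):

        def backward(g, ts=tuple(tensors), ax=axis):
            for i, t in enumerate(ts):
                t._acc(np.take(g, i, axis=ax))

        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out
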
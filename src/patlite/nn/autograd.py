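"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an
``ndarray`` and records, for each produced value, a closure that routes the
upstream gradient to its parents.  Only the operations needed by the
actigraphy transformer are implemented (broadcast arithmetic, batched
matmul, reshape/transpose, reductions, softmax, gather/scatter along the
token axis, and a few pointwise nonlinearities).  Everything runs in
float64; gradients are checked against central finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "softmax", "softplus",
           "take_windows", "gather_tokens", "assemble_tokens"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep tapes overflow recursion limits
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

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g, b.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            def bw(g, a=self):
                a._accumulate(-g)
            out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(g * a.data, b.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = _make(self.data ** exponent, (self,))
        if out.requires_grad:
            def bw(g, a=self, e=exponent):
                a._accumulate(g * e * a.data ** (e - 1.0))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bw(g, a=self, b=other):
                if a.requires_grad:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accumulate(_unbroadcast(ga, a.data.shape))
                if b.requires_grad:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accumulate(_unbroadcast(gb, b.data.shape))
            out._backward = bw
        return out

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            def bw(g, a=self):
                a._accumulate(g.reshape(a.data.shape))
            out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            def bw(g, a=self, inv=tuple(inv)):
                a._accumulate(g.transpose(inv))
            out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- pointwise
    def exp(self):
        val = np.exp(self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            def bw(g, a=self, v=val):
                a._accumulate(g * v)
            out._backward = bw
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            def bw(g, a=self):
                a._accumulate(g / a.data)
            out._backward = bw
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            def bw(g, a=self, v=val):
                a._accumulate(g * (1.0 - v * v))
            out._backward = bw
        return out

    def relu(self):
        val = np.maximum(self.data, 0.0)
        out = _make(val, (self,))
        if out.requires_grad:
            mask = (self.data > 0.0).astype(np.float64)
            def bw(g, a=self, m=mask):
                a._accumulate(g * m)
            out._backward = bw
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(val, (self,))
        if out.requires_grad:
            def bw(g, a=self, v=val):
                a._accumulate(g * v * (1.0 - v))
            out._backward = bw
        return out


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
    return out


# ---------------------------------------------------------------- free ops
def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g, ts=tensors, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (x,))
    if out.requires_grad:
        def bw(g, a=x, s=s, axis=axis):
            inner = (g * s).sum(axis=axis, keepdims=True)
            a._accumulate((g - inner) * s)
        out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable; d/dx = sigmoid(x)."""
    out = _make(np.logaddexp(0.0, x.data), (x,))
    if out.requires_grad:
        sig = 1.0 / (1.0 + np.exp(-x.data))
        def bw(g, a=x, s=sig):
            a._accumulate(g * s)
        out._backward = bw
    return out


def take_windows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather sliding windows along axis 1.

    ``x`` has shape (B, L, C) and ``idx`` shape (L_out, K) of integer indices
    into axis 1; the result has shape (B, L_out, K, C).  Used for im2col-style
    1D convolution.
    """
    idx = np.asarray(idx)
    out = _make(x.data[:, idx], (x,))
    if out.requires_grad:
        def bw(g, a=x, idx=idx):
            gx = np.zeros_like(a.data)
            np.add.at(gx, (slice(None), idx), g)
            a._accumulate(gx)
        out._backward = bw
    return out


def gather_tokens(x: Tensor, idx: np.ndarray) -> Tensor:
    """Batched gather along the token axis.

    ``x``: (B, N, D); ``idx``: (B, V) integer indices; result (B, V, D) with
    ``out[b, i] = x[b, idx[b, i]]``.
    """
    idx = np.asarray(idx)
    out = _make(np.take_along_axis(x.data, idx[:, :, None], axis=1), (x,))
    if out.requires_grad:
        B = x.data.shape[0]
        rows = np.arange(B)[:, None]
        def bw(g, a=x, idx=idx, rows=rows):
            gx = np.zeros_like(a.data)
            np.add.at(gx, (rows, idx), g)
            a._accumulate(gx)
        out._backward = bw
    return out


def assemble_tokens(visible: Tensor, token: Tensor, idx: np.ndarray, n_total: int) -> Tensor:
    """Re-insert visible tokens into a full sequence of mask tokens.

    ``visible``: (B, V, D) encoder outputs; ``token``: (D,) shared learned
    mask token; ``idx``: (B, V) the positions the visible tokens came from.
    Result (B, N, D): mask token everywhere except ``idx``.
    """
    idx = np.asarray(idx)
    B, V, D = visible.data.shape
    base = np.broadcast_to(token.data, (B, n_total, D)).copy()
    rows = np.arange(B)[:, None]
    base[rows, idx] = visible.data
    out = _make(base, (visible, token))
    if out.requires_grad:
        def bw(g, v=visible, t=token, idx=idx, rows=rows):
            g_vis = g[rows, idx]
            if v.requires_grad:
                v._accumulate(g_vis)
            if t.requires_grad:
                t._accumulate(g.sum(axis=(0, 1)) - g_vis.sum(axis=(0, 1)))
        out._backward = bw
    return out


def check_finite(x: Tensor, what: str = "input") -> Tensor:
    if not np.all(np.isfinite(x.data)):
        raise FloatingPointError(f"non-finite values in {what}")
    return x
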
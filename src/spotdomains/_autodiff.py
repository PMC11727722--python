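"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the graph-attention autoencoder,
the self-expression module, and the classifier head: dense linear algebra,
pointwise nonlinearities, segment (per-neighborhood) reductions for edge
softmax, and scatter/gather for sparse message passing. Everything is
float64 and single-threaded-deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


class Tensor:
    """Node in the computation tape.

    ``parents`` is a list of ``(parent, grad_fn)`` pairs where ``grad_fn``
    maps the upstream gradient to this parent's gradient contribution.
    """

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or bool(parents)
        self.parents = parents or []

    @property
    def shape(self):
        return self.data.shape

    # ---- graph plumbing -------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.grad is None:
                continue
            for p, fn in t.parents:
                if not p.requires_grad:
                    continue
                g = fn(t.grad)
                p.grad = g if p.grad is None else p.grad + g

    # ---- operators ------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=[
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(g, other.data.shape)),
        ])
        return out

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data - other.data, parents=[
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(-g, other.data.shape)),
        ])

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data * other.data, parents=[
            (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
            (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
        ])

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(self.data / other.data, parents=[
            (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
            (other, lambda g: _unbroadcast(-g * self.data / other.data ** 2,
                                           other.data.shape)),
        ])

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __neg__(self):
        return Tensor(-self.data, parents=[(self, lambda g: -g)])

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data
        a2 = a[None, :] if a.ndim == 1 else a
        b2 = b[:, None] if b.ndim == 1 else b

        def back_a(g):
            g2 = g.reshape(a2.shape[0], b2.shape[1])
            ga = g2 @ b2.T
            return ga[0] if a.ndim == 1 else ga

        def back_b(g):
            g2 = g.reshape(a2.shape[0], b2.shape[1])
            gb = a2.T @ g2
            return gb[:, 0] if b.ndim == 1 else gb

        return Tensor(a @ b, parents=[(self, back_a), (other, back_b)])

    @property
    def T(self):
        return Tensor(self.data.T, parents=[(self, lambda g: g.T)])

    # ---- nonlinearities -------------------------------------------------

    def elu(self):
        x = self.data
        y = np.where(x > 0, x, np.expm1(x))
        return Tensor(y, parents=[(self, lambda g: g * np.where(x > 0, 1.0, y + 1.0))])

    def relu(self):
        x = self.data
        return Tensor(np.maximum(x, 0.0), parents=[(self, lambda g: g * (x > 0))])

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(s, parents=[(self, lambda g: g * s * (1.0 - s))])

    def softplus(self):
        x = self.data
        y = np.logaddexp(0.0, x)
        s = 1.0 / (1.0 + np.exp(-x))
        return Tensor(y, parents=[(self, lambda g: g * s)])

    def exp(self):
        y = np.exp(self.data)
        return Tensor(y, parents=[(self, lambda g: g * y)])

    def log(self):
        x = self.data
        return Tensor(np.log(x), parents=[(self, lambda g: g / x)])

    def abs(self):
        x = self.data
        return Tensor(np.abs(x), parents=[(self, lambda g: g * np.sign(x))])

    def clip(self, lo, hi):
        x = self.data
        mask = (x >= lo) & (x <= hi)
        return Tensor(np.clip(x, lo, hi), parents=[(self, lambda g: g * mask)])

    # ---- reductions -----------------------------------------------------

    def sum(self):
        shape = self.data.shape
        return Tensor(self.data.sum(), parents=[
            (self, lambda g: np.broadcast_to(g, shape).copy())])

    def sumsq(self):
        """sum of squared entries (squared Frobenius norm)."""
        x = self.data
        return Tensor((x * x).sum(), parents=[(self, lambda g: g * 2.0 * x)])

    def frob(self):
        """Frobenius norm; gradient guarded at zero."""
        x = self.data
        nrm = float(np.sqrt((x * x).sum()))
        safe = max(nrm, 1e-30)
        return Tensor(nrm, parents=[(self, lambda g: g * x / safe)])

    def sum_rows(self):
        """(n, d) -> (n, 1) row sums."""
        n, d = self.data.shape
        return Tensor(self.data.sum(axis=1, keepdims=True), parents=[
            (self, lambda g: np.repeat(g, d, axis=1))])

    # ---- indexing / segment ops ----------------------------------------

    def rows(self, idx):
        """Gather rows; scatter-add gradient."""
        idx = np.asarray(idx)
        shape = self.data.shape

        def back(g):
            out = np.zeros(shape)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], parents=[(self, back)])

    def take(self, idx):
        """Gather entries of a vector."""
        idx = np.asarray(idx)
        size = self.data.shape

        def back(g):
            out = np.zeros(size)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], parents=[(self, back)])

    def take_per_row(self, cols):
        """(n, m) -> (n,) picking entry ``cols[i]`` from row i."""
        n, m = self.data.shape
        cols = np.asarray(cols)
        rows = np.arange(n)

        def back(g):
            out = np.zeros((n, m))
            out[rows, cols] = g
            return out

        return Tensor(self.data[rows, cols], parents=[(self, back)])

    def segment_sum(self, seg, n_segments):
        """(E,) -> (n_segments,) summing entries by segment id."""
        seg = np.asarray(seg)
        y = np.zeros(n_segments)
        np.add.at(y, seg, self.data)
        return Tensor(y, parents=[(self, lambda g: g[seg])])

    def scatter_to(self, idx, size):
        """(E_sub,) -> (size,) placing entries at ``idx``, zeros elsewhere."""
        idx = np.asarray(idx)
        y = np.zeros(size)
        y[idx] = self.data
        return Tensor(y, parents=[(self, lambda g: g[idx])])


def edge_aggregate(att, M, src, dst, n):
    """out[i] = sum over edges e with dst[e]==i of att[e] * M[src[e]].

    ``att`` is an (E,) Tensor of edge weights, ``M`` an (n, d) Tensor of
    messages; returns an (n, d) Tensor.
    """
    src = np.asarray(src)
    dst = np.asarray(dst)
    a, m = att.data, M.data
    out = np.zeros((n, m.shape[1]))
    np.add.at(out, dst, a[:, None] * m[src])

    def back_att(g):
        return (g[dst] * m[src]).sum(axis=1)

    def back_m(g):
        gm = np.zeros_like(m)
        np.add.at(gm, src, a[:, None] * g[dst])
        return gm

    return Tensor(out, parents=[(att, back_att), (M, back_m)])


def segment_softmax(logits, seg, n_segments):
    """Softmax of an (E,) Tensor within segments (numerically safe: the
    logits here are sigmoid outputs in (0, 1), so no max-shift is needed)."""
    e = logits.exp()
    denom = e.segment_sum(seg, n_segments)
    return e / denom.take(seg)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = g.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Adam:
    """Standard Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
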
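"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the relational GNN encoder, the attention
combination encoder and the convolutional decoder need: broadcasting
arithmetic, (batched) dense matmul, sparse-dense products for gather /
scatter / segment reductions, pointwise nonlinearities, reductions,
reshapes and a numerically stable binary cross-entropy with logits.

Gradients for broadcasting ops are reduced back to the operand's shape;
sparse products use scipy CSR matrices held as constants, so graph
gather/aggregate structure is built once per topology and reused across
training steps.  Correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import contextlib

import numpy as np
import scipy.sparse as sp

_DTYPE = np.float64


def default_dtype():
    return _DTYPE


@contextlib.contextmanager
def dtype(dt):
    """Temporarily switch the dtype newly created tensors use.

    Training runs in float32 for speed; gradient-check tests and eval-time
    scoring default to float64.
    """
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dt).type
    try:
        yield
    finally:
        _DTYPE = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad=False, parents=(), bwd=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._bwd = bwd

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self, grad=None):
        """Accumulate gradients of `self` (a scalar unless grad given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen and (p.requires_grad or p._parents):
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def param(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def _accum(t: Tensor, g: np.ndarray) -> None:
    # grads are never mutated in place, so sharing the incoming array is safe
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.asarray(g, dtype=t.data.dtype)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _make(data, parents, bwd) -> Tensor:
    track = any(p.requires_grad or p._parents for p in parents)
    return Tensor(data, parents=tuple(parents) if track else (),
                  bwd=bwd if track else None)


# ---------------------------------------------------------------- arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def bwd(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(out_data, (a, b), bwd)


def powc(a: Tensor, p: float) -> Tensor:
    out_data = a.data ** p

    def bwd(g):
        _accum(a, g * p * a.data ** (p - 1))

    return _make(out_data, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Dense matmul; supports (..., m, k) @ (k, n) and 2-D @ 2-D."""
    out_data = a.data @ b.data

    def bwd(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        _accum(a, _unbroadcast(ga, a.data.shape))
        if a.data.ndim > 2 and b.data.ndim == 2:
            k = a.data.shape[-1]
            gb = a.data.reshape(-1, k).T @ g.reshape(-1, g.shape[-1])
        else:
            gb = np.swapaxes(a.data, -1, -2) @ g
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), bwd)


def spmm(A: sp.spmatrix, x: Tensor) -> Tensor:
    """Constant sparse (m, n) times tensor (n, k): gather/scatter/segment-sum."""
    A = A.tocsr()
    if A.dtype != x.data.dtype:
        Ac = getattr(A, "_cast", None)
        if Ac is None or Ac.dtype != x.data.dtype:
            Ac = A.astype(x.data.dtype)
            try:
                A._cast = Ac
            except AttributeError:
                pass
        A = Ac
    out_data = A @ x.data

    def bwd(g):
        At = getattr(A, "_cached_T", None)
        if At is None:
            At = A.T.tocsr()
            try:
                A._cached_T = At
            except AttributeError:
                pass
        _accum(x, At @ g)

    return _make(out_data, (x,), bwd)


# ------------------------------------------------------------- nonlinearities

def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bwd(g):
        _accum(a, g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), bwd)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0.0)

    def bwd(g):
        _accum(a, g * (a.data > 0))

    return _make(out_data, (a,), bwd)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    out_data = np.where(a.data > 0, a.data, slope * a.data)

    def bwd(g):
        _accum(a, g * np.where(a.data > 0, 1.0, slope))

    return _make(out_data, (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def bwd(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bwd)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bwd(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), bwd)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def bwd(g):
        _accum(a, g / a.data)

    return _make(out_data, (a,), bwd)


def identity(a: Tensor) -> Tensor:
    return a


ACTIVATIONS = {"tanh": tanh, "relu": relu, "identity": identity, "sigmoid": sigmoid}


# ------------------------------------------------------------------ reshaping

def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)
    orig = a.data.shape

    def bwd(g):
        _accum(a, g.reshape(orig))

    return _make(out_data, (a,), bwd)


def transpose(a: Tensor, axes=None) -> Tensor:
    out_data = np.transpose(a.data, axes)
    inv = None if axes is None else np.argsort(axes)

    def bwd(g):
        _accum(a, np.transpose(g, inv))

    return _make(out_data, (a,), bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), bwd)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    shape = a.data.shape

    def bwd(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, shape).copy())

    return _make(out_data, (a,), bwd)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), _as_tensor(1.0 / n))


def ccorr(a: Tensor, b: Tensor) -> Tensor:
    """Circular correlation along the last axis: out[..., k] = sum_d a[..., d] b[..., (d+k) % K]."""
    fa = np.fft.rfft(a.data, axis=-1)
    fb = np.fft.rfft(b.data, axis=-1)
    K = a.data.shape[-1]
    out_data = np.fft.irfft(np.conj(fa) * fb, n=K, axis=-1)

    def bwd(g):
        fg = np.fft.rfft(g, axis=-1)
        # d/da: correlate g with b forward; d/db: circular convolution of a and g
        _accum(a, np.fft.irfft(np.conj(fg) * fb, n=K, axis=-1))
        _accum(b, np.fft.irfft(fa * fg, n=K, axis=-1))

    return _make(out_data, (a, b), bwd)


def bce_with_logits(
    scores: Tensor, targets: np.ndarray, pos_weight: float | None = None
) -> Tensor:
    """Weighted-mean binary cross-entropy from logits, numerically stable.

    L = sum(w * (max(s, 0) - s*y + log(1 + exp(-|s|)))) / sum(w), with
    w = 1 for negatives and w = pos_weight for positives.  Weighting the
    scarce positives keeps 1-vs-all training off the trivial all-negative
    optimum when candidates vastly outnumber true tails.
    """
    s, y = scores.data, np.asarray(targets, dtype=np.float64)
    loss = np.maximum(s, 0) - s * y + np.log1p(np.exp(-np.abs(s)))
    if pos_weight is None or pos_weight == 1.0:
        w = None
        wsum = s.size
        out_data = np.array(loss.sum() / wsum)
    else:
        w = 1.0 + (pos_weight - 1.0) * y
        wsum = w.sum()
        out_data = np.array((w * loss).sum() / wsum)

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))
        grad = (p - y) if w is None else w * (p - y)
        _accum(scores, (float(g) / wsum) * grad)

    return _make(out_data, (scores,), bwd)


# -------------------------------------------------------------- sparse helpers

def rows_onehot(idx: np.ndarray, n_cols: int) -> sp.csr_matrix:
    """G (len(idx), n_cols) with G[e, idx[e]] = 1: spmm(G, X) gathers rows."""
    idx = np.asarray(idx, dtype=np.int64)
    return sp.csr_matrix(
        (np.ones(len(idx), dtype=_DTYPE), (np.arange(len(idx)), idx)),
        shape=(len(idx), n_cols),
    )


def segment_matrix(seg: np.ndarray, n_seg: int, weights: np.ndarray | None = None) -> sp.csr_matrix:
    """A (n_seg, len(seg)): spmm(A, X) sums (or weight-averages) rows by segment."""
    seg = np.asarray(seg, dtype=np.int64)
    w = np.ones(len(seg), dtype=_DTYPE) if weights is None else np.asarray(weights, dtype=_DTYPE)
    return sp.csr_matrix((w, (seg, np.arange(len(seg)))), shape=(n_seg, len(seg)))


def segment_softmax(logits: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Softmax of a (E, 1) logit column within segments given by `seg`.

    The per-segment max is treated as a constant shift (standard stabilised
    softmax; the shift has zero gradient contribution).
    """
    seg = np.asarray(seg, dtype=np.int64)
    mx = np.full(n_seg, -np.inf)
    np.maximum.at(mx, seg, logits.data[:, 0])
    shifted = sub(logits, constant(mx[seg][:, None]))
    ez = exp(shifted)
    A = segment_matrix(seg, n_seg)
    denom = spmm(A, ez)               # (n_seg, 1)
    G = rows_onehot(seg, n_seg)
    return div(ez, spmm(G, denom))


# ------------------------------------------------------------------- optimiser

class Adam:
    """Adam with decoupled L2 weight decay over a dict of Tensors."""

    def __init__(self, params: dict[str, Tensor], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0, lr_scales: dict[str, float] | None = None):
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.lr_scales = lr_scales or {}
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            lr = self.lr * self.lr_scales.get(k, 1.0)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


def xavier_normal(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Xavier-normal init: std = sqrt(2 / (fan_in + fan_out))."""
    if len(shape) == 2:
        fan_in, fan_out = shape
    else:
        fan_in = fan_out = shape[-1]
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape)
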
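"""Minimal reverse-mode automatic differentiation over numpy arrays.

Every operation here is *dual dispatch*: if no argument is a :class:`Tensor`
the plain numpy result is returned with zero tape overhead, so the same model
code serves both the training path (gradients) and the inference path (raw
numpy speed and memory). Gradients are validated against central finite
differences in the test suite.

Only the operations the attention network needs are implemented; this is not
a general framework. All computation is float64.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor", "add", "sub", "mul", "div", "neg", "matmul", "channel_matmul",
    "concat", "reduce_sum", "reduce_mean", "log", "exp", "sqrt", "clip_min",
    "relu", "sigmoid", "softmax", "layer_norm", "gather", "gather_pairs",
    "gather_attention", "edge_bias_matrix", "broadcast_middle", "expand_last",
    "transpose2d", "data_of",
]


class Tensor:
    """A node in the computation tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # arithmetic sugar used sparingly in model code
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor; accumulates ``.grad`` on all leaves."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate into .grad
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)

def data_of(x):
    """Underlying ndarray of a Tensor, or the input coerced to float64."""
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data, parents, backward):
    if any(_is_tensor(p) for p in parents):
        tensors = tuple(p for p in parents if _is_tensor(p))
        # backward receives upstream grad and must return grads aligned with
        # *all* parents; non-Tensor parents get their slot dropped here.
        def bw(g, _parents=parents, _backward=backward):
            all_grads = _backward(g)
            return [gr for p, gr in zip(_parents, all_grads) if _is_tensor(p)]
        return Tensor(data, tensors, bw)
    return data


# ---------------------------------------------------------------- arithmetic

def add(a, b):
    ad, bd = data_of(a), data_of(b)
    out = ad + bd
    return _make(out, (a, b), lambda g: (_unbroadcast(g, ad.shape), _unbroadcast(g, bd.shape)))


def sub(a, b):
    ad, bd = data_of(a), data_of(b)
    out = ad - bd
    return _make(out, (a, b), lambda g: (_unbroadcast(g, ad.shape), _unbroadcast(-g, bd.shape)))


def neg(a):
    return _make(-data_of(a), (a,), lambda g: (-g,))


def mul(a, b):
    ad, bd = data_of(a), data_of(b)
    out = ad * bd
    return _make(out, (a, b), lambda g: (_unbroadcast(g * bd, ad.shape), _unbroadcast(g * ad, bd.shape)))


def div(a, b):
    ad, bd = data_of(a), data_of(b)
    out = ad / bd
    def bw(g):
        return (_unbroadcast(g / bd, ad.shape), _unbroadcast(-g * ad / (bd * bd), bd.shape))
    return _make(out, (a, b), bw)


def matmul(a, b):
    """``a @ b`` where ``b`` is a 2-D weight matrix and ``a`` has any rank >= 1."""
    ad, bd = data_of(a), data_of(b)
    if bd.ndim != 2:
        raise ValueError("matmul: right operand must be 2-D")
    out = ad @ bd
    def bw(g):
        ga = g @ bd.T
        axes = list(range(ad.ndim - 1))
        gb = np.tensordot(ad, g, axes=(axes, axes))
        return (ga, gb)
    return _make(out, (a, b), bw)


def channel_matmul(v, w):
    """Mix vector channels: ``einsum('...ic,ij->...jc', v, w)``.

    ``v`` holds 3-vectors in its last axis and channels in the second-to-last;
    the mixing is linear over channels so rotation equivariance is preserved.
    """
    vd, wd = data_of(v), data_of(w)
    out = np.einsum("...ic,ij->...jc", vd, wd)
    def bw(g):
        gv = np.einsum("...jc,ij->...ic", g, wd)
        vflat = vd.reshape(-1, vd.shape[-2], vd.shape[-1])
        gflat = g.reshape(-1, g.shape[-2], g.shape[-1])
        gw = np.einsum("bic,bjc->ij", vflat, gflat)
        return (gv, gw)
    return _make(out, (v, w), bw)


def transpose2d(a):
    ad = data_of(a)
    return _make(ad.T, (a,), lambda g: (g.T,))


def concat(parts: Sequence, axis: int = -1):
    datas = [data_of(p) for p in parts]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        return tuple(np.split(g, splits, axis=axis))
    return _make(out, tuple(parts), bw)


def reduce_sum(a, axis=None, keepdims: bool = False):
    ad = data_of(a)
    out = ad.sum(axis=axis, keepdims=keepdims)
    def bw(g):
        if axis is None:
            return (np.broadcast_to(g, ad.shape).copy(),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        return (np.broadcast_to(gg, ad.shape).copy(),)
    return _make(out, (a,), bw)


def reduce_mean(a, axis=None, keepdims: bool = False):
    ad = data_of(a)
    if axis is None:
        n = ad.size
    else:
        n = ad.shape[axis]
    return mul(reduce_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# ------------------------------------------------------------ element-wise

def log(a):
    ad = data_of(a)
    return _make(np.log(ad), (a,), lambda g: (g / ad,))


def exp(a):
    ad = data_of(a)
    out = np.exp(ad)
    return _make(out, (a,), lambda g: (g * out,))


def sqrt(a):
    ad = data_of(a)
    out = np.sqrt(ad)
    return _make(out, (a,), lambda g: (g / (2.0 * out),))


def clip_min(a, lo: float):
    """Elementwise ``max(a, lo)``; gradient flows only where ``a > lo``."""
    ad = data_of(a)
    out = np.maximum(ad, lo)
    return _make(out, (a,), lambda g: (g * (ad > lo),))


def relu(a):
    ad = data_of(a)
    return _make(np.maximum(ad, 0.0), (a,), lambda g: (g * (ad > 0),))


def sigmoid(a):
    ad = data_of(a)
    out = 1.0 / (1.0 + np.exp(-ad))
    return _make(out, (a,), lambda g: (g * out * (1.0 - out),))


def expand_last(a):
    """Append a trailing length-1 axis (for gating 3-vectors by scalars)."""
    ad = data_of(a)
    return _make(ad[..., None], (a,), lambda g: (g[..., 0],))


# -------------------------------------------------------------- structured

def softmax(a, axis: int = -1):
    ad = data_of(a)
    shifted = ad - ad.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)
    def bw(g):
        return ((g - (g * out).sum(axis=axis, keepdims=True)) * out,)
    return _make(out, (a,), bw)


def layer_norm(x, gain, offset, eps: float = 1e-5):
    """Layer normalization over the last axis with learned gain and offset."""
    xd, gd, od = data_of(x), data_of(gain), data_of(offset)
    mu = xd.mean(axis=-1, keepdims=True)
    xc = xd - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gd + od
    def bw(g):
        batch_axes = tuple(range(xd.ndim - 1))
        ggain = (g * xhat).sum(axis=batch_axes)
        goff = g.sum(axis=batch_axes)
        dxhat = g * gd
        gx = (dxhat - dxhat.mean(axis=-1, keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)) * inv
        return (gx, ggain, goff)
    return _make(out, (x, gain, offset), bw)


def gather(table, index: np.ndarray):
    """``table[index]`` along axis 0 (embedding lookup / neighbor gather)."""
    td = data_of(table)
    idx = np.asarray(index)
    out = td[idx]
    def bw(g):
        gt = np.zeros_like(td)
        np.add.at(gt, idx, g)
        return (gt,)
    return _make(out, (table,), bw)


def gather_pairs(x, rows: np.ndarray, cols: np.ndarray):
    """``x[rows, cols]`` for a 2-D operand (e.g. per-position probabilities)."""
    xd = data_of(x)
    out = xd[rows, cols]
    def bw(g):
        gx = np.zeros_like(xd)
        np.add.at(gx, (rows, cols), g)
        return (gx,)
    return _make(out, (x,), bw)


def gather_attention(attn, neighbor_index: np.ndarray):
    """Select neighbor columns from an (N, N) attention matrix -> (N, k)."""
    ad = data_of(attn)
    n = ad.shape[0]
    rows = np.arange(n)[:, None]
    out = ad[rows, neighbor_index]
    def bw(g):
        ga = np.zeros_like(ad)
        np.add.at(ga, (np.broadcast_to(rows, neighbor_index.shape), neighbor_index), g)
        return (ga,)
    return _make(out, (attn,), bw)


def edge_bias_matrix(neighbor_bias, pseudo_bias, neighbor_index: np.ndarray, n: int):
    """Build the full (N, N) attention-bias matrix from sparse edge biases.

    Entry (i, j) is ``neighbor_bias[i, slot]`` when j is the slot-th neighbor
    of i, and the scalar ``pseudo_bias`` everywhere else (including the
    diagonal: a residue is never its own graph neighbor). Used only on the
    training path, where N is small; inference streams the pseudo value
    implicitly without materializing this matrix.
    """
    nb = data_of(neighbor_bias)
    pb = data_of(pseudo_bias)
    rows = np.arange(n)[:, None]
    out = np.full((n, n), float(pb))
    if neighbor_index.size:
        out[np.broadcast_to(rows, neighbor_index.shape), neighbor_index] = nb
    def bw(g):
        if neighbor_index.size:
            gnb = g[np.broadcast_to(rows, neighbor_index.shape), neighbor_index]
            gpb = g.sum() - gnb.sum()
        else:
            gnb = np.zeros_like(nb)
            gpb = g.sum()
        return (gnb, np.asarray(gpb))
    return _make(out, (neighbor_bias, pseudo_bias), bw)


def broadcast_middle(x, k: int):
    """(N, d) -> (N, k, d) by repetition along a new middle axis."""
    xd = data_of(x)
    out = np.broadcast_to(xd[:, None, :], (xd.shape[0], k, xd.shape[1])).copy()
    return _make(out, (x,), lambda g: (g.sum(axis=1),))
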
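"""Compact reverse-mode automatic differentiation over NumPy float32 arrays.

Covers exactly the operations the sleep-staging network needs: broadcast
arithmetic, matmul, strided 1-D convolution (im2col + BLAS), ReLU,
sigmoid, tanh, log-softmax, adaptive average pooling, concatenation,
index selection, dropout, and reductions. Gradients are checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=DTYPE)
        self.grad = g if self.grad is None else self.grad + g

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

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __truediv__(self, scalar):
        return mul(self, 1.0 / float(scalar))

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None):
        return tsum(self, axis)

    def mean(self, axis=None):
        return tmean(self, axis)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


# -- primitives ------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a = as_tensor(a)
    if not isinstance(b, Tensor):
        bval = np.asarray(b, dtype=DTYPE)

        def bw_scalar(g):
            a._accumulate(_unbroadcast(g * bval, a.data.shape))

        return _node(a.data * bval, (a,), bw_scalar)

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), bw)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _node(a.data @ b.data, (a, b), bw)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def bw(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # overflow-safe logistic
    y = np.empty_like(a.data)
    pos = a.data >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    y[~pos] = ex / (1.0 + ex)

    def bw(g):
        a._accumulate(g * y * (1.0 - y))

    return _node(y, (a,), bw)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)

    def bw(g):
        a._accumulate(g * (1.0 - y * y))

    return _node(y, (a,), bw)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape

    def bw(g):
        a._accumulate(g.reshape(old))

    return _node(a.data.reshape(shape), (a,), bw)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def tsum(a, axis=None) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape))
        else:
            a._accumulate(np.broadcast_to(np.expand_dims(g, axis), a.data.shape))

    return _node(a.data.sum(axis=axis), (a,), bw)


def tmean(a, axis=None) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis), 1.0 / n)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    y = shifted - logz

    def bw(g):
        softmax = np.exp(y)
        a._accumulate(g - softmax * g.sum(axis=axis, keepdims=True))

    return _node(y, (a,), bw)


def select_rows(a, index: np.ndarray) -> Tensor:
    """Pick a[i, index[i]] for each row i; returns shape (n,)."""
    a = as_tensor(a)
    index = np.asarray(index, dtype=np.int64)
    rows = np.arange(a.data.shape[0])

    def bw(g):
        full = np.zeros_like(a.data)
        full[rows, index] = g
        a._accumulate(full)

    return _node(a.data[rows, index], (a,), bw)


def take_rows(a, indices: np.ndarray) -> Tensor:
    """Gather rows of a 2-D tensor by index, differentiably."""
    a = as_tensor(a)
    indices = np.asarray(indices, dtype=np.int64)

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, indices, g)
        a._accumulate(full)

    return _node(a.data[indices], (a,), bw)


def slice_rows(a, start: int, stop: int) -> Tensor:
    """View rows [start:stop) of a 2-D tensor, differentiably."""
    a = as_tensor(a)

    def bw(g):
        full = np.zeros_like(a.data)
        full[start:stop] = g
        a._accumulate(full)

    return _node(a.data[start:stop], (a,), bw)


def dropout(a, p: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return as_tensor(a)
    if rng is None:
        raise ValueError("dropout in training mode needs an rng")
    a = as_tensor(a)
    mask = (rng.random(a.data.shape) >= p).astype(DTYPE) / (1.0 - p)

    def bw(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), bw)


def conv1d(x, w, b, stride: int = 1, padding: int = 0) -> Tensor:
    """x: (N, C_in, L); w: (C_out, C_in, K); b: (C_out,) -> (N, C_out, L_out)."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    n, c_in, length = x.data.shape
    c_out, _, k = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    lp = xp.shape[2]
    l_out = (lp - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::stride]
    # (N, C_in, L_out, K) -> (N*L_out, C_in*K) for a single BLAS call
    col = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(n * l_out, c_in * k)
    wmat = w.data.reshape(c_out, c_in * k)
    out = (col @ wmat.T + b.data).reshape(n, l_out, c_out).transpose(0, 2, 1)

    def bw(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(n * l_out, c_out)
        w._accumulate((gmat.T @ col).reshape(c_out, c_in, k))
        b._accumulate(gmat.sum(axis=0))
        dcol = (gmat @ wmat).reshape(n, l_out, c_in, k).transpose(0, 2, 1, 3)
        dxp = np.zeros((n, c_in, lp), dtype=DTYPE)
        for kk in range(k):
            dxp[:, :, kk: kk + stride * l_out: stride] += dcol[:, :, :, kk]
        x._accumulate(dxp[:, :, padding: lp - padding] if padding else dxp)

    return _node(out, (x, w, b), bw)


def adaptive_avg_pool1d(x, out_len: int) -> Tensor:
    """Average (N, C, L) down to (N, C, out_len) over near-equal bins."""
    x = as_tensor(x)
    n, c, length = x.data.shape
    starts = (np.arange(out_len) * length) // out_len
    ends = ((np.arange(out_len) + 1) * length + out_len - 1) // out_len
    out = np.empty((n, c, out_len), dtype=DTYPE)
    for i in range(out_len):
        out[:, :, i] = x.data[:, :, starts[i]: ends[i]].mean(axis=2)

    def bw(g):
        dx = np.zeros((n, c, length), dtype=DTYPE)
        for i in range(out_len):
            width = ends[i] - starts[i]
            dx[:, :, starts[i]: ends[i]] += g[:, :, i: i + 1] / width
        x._accumulate(dx)

    return _node(out, (x,), bw)
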
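"""Minimal reverse-mode autodiff on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records a closure that
propagates gradients to its parents; :meth:`Tensor.backward` runs the
closures in reverse topological order. Only the operations the pose network
needs are provided: broadcast add/mul/sub, matmul, conv2d (strided,
grouped), relu/sigmoid, sums/means, global average pooling, nearest ×2
upsampling, and space-to-depth. Convolution is im2col + matmul in both
directions, so everything reduces to BLAS calls.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad down to ``shape`` (inverse of numpy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        # float32 throughout the network; float64 inputs keep their
        # precision (used by the numeric gradient checks)
        arr = np.asarray(data)
        if arr.dtype != np.float64:
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---- arithmetic ----
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def square(self):
        out = Tensor(self.data ** 2, self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(2.0 * self.data * g)
        return out

    def sum(self):
        out = Tensor(self.data.sum(), self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(
            np.broadcast_to(g / n, self.data.shape))
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad,
                     parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def matmul(self, other: "Tensor"):
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad or other._parents:
                other._accum(self.data.swapaxes(-1, -2) @ g)
        out._backward = bw
        return out

    # ---- nonlinearities ----
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -30, 30)))
        out = Tensor(s, self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1 - s))
        return out

    # ---- spatial ops (NCHW) ----
    def global_avg_pool(self):
        """(N, C, H, W) -> (N, C, 1, 1) mean over the spatial dims."""
        n, c, h, w = self.data.shape
        out = Tensor(self.data.mean(axis=(2, 3), keepdims=True),
                     self.requires_grad, parents=(self,))
        out._backward = lambda g: self._accum(
            np.broadcast_to(g / (h * w), self.data.shape))
        return out

    def upsample2(self):
        """Nearest-neighbour x2 upsampling of (N, C, H, W)."""
        d = self.data
        up = d.repeat(2, axis=2).repeat(2, axis=3)
        out = Tensor(up, self.requires_grad, parents=(self,))

        def bw(g):
            n, c, h2, w2 = g.shape
            self._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))
        out._backward = bw
        return out

    def space_to_depth(self):
        """(N, C, H, W) -> (N, 4C, H/2, W/2): stack the 4 pixel-parity grids."""
        n, c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError("space_to_depth needs even H and W")
        d = self.data
        parts = [d[:, :, 0::2, 0::2], d[:, :, 0::2, 1::2],
                 d[:, :, 1::2, 0::2], d[:, :, 1::2, 1::2]]
        out = Tensor(np.concatenate(parts, axis=1), self.requires_grad,
                     parents=(self,))

        def bw(g):
            gx = np.zeros_like(d)
            gs = np.split(g, 4, axis=1)
            gx[:, :, 0::2, 0::2] = gs[0]
            gx[:, :, 0::2, 1::2] = gs[1]
            gx[:, :, 1::2, 0::2] = gs[2]
            gx[:, :, 1::2, 1::2] = gs[3]
            self._accum(gx)
        out._backward = bw
        return out


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, C, k, k, Ho, Wo) patch stack (9 strided copies)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c = x.shape[:2]
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i:i + stride * ho:stride,
                                 j:j + stride * wo:stride]
    return cols, ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col`; cols is (N, C, k, k, Ho, Wo)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


def conv2d(x: Tensor, w: Tensor, b: Tensor = None, stride: int = 1,
           pad: int = None, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution. w is (Cout, Cin/groups, k, k).

    im2col once, then one batched GEMM over the group axis; the backward
    pass is the pair of adjoint GEMMs plus col2im scatter-adds.
    """
    cout, cin_g, k, _ = w.data.shape
    n, cin, h, wdt = x.data.shape
    if cin != cin_g * groups:
        raise ValueError("channel/group mismatch")
    if pad is None:
        pad = k // 2
    co_g = cout // groups
    kk = cin_g * k * k
    cols6, ho, wo = _im2col(x.data, k, stride, pad)
    L = ho * wo
    cols = cols6.reshape(n, groups, kk, L)
    w2 = w.data.reshape(groups, co_g, kk)
    y = np.matmul(w2, cols)                       # (N, G, co_g, L)
    y = y.reshape(n, cout, ho, wo)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, any(p.requires_grad or p._parents for p in parents),
                 parents=parents)

    def bw(g_out):
        gy = g_out.reshape(n, groups, co_g, L)
        if b is not None and (b.requires_grad or b._parents):
            b._accum(g_out.sum(axis=(0, 2, 3)))
        if w.requires_grad or w._parents:
            gw = np.matmul(gy, cols.swapaxes(-1, -2)).sum(axis=0)  # (G,co_g,kk)
            if w.grad is None:
                w.grad = np.zeros_like(w.data)
            w.grad += gw.reshape(w.data.shape)
        if x.requires_grad or x._parents:
            gcols = np.matmul(w2.swapaxes(-1, -2), gy)   # (N, G, kk, L)
            gcols = gcols.reshape(n, cin, k, k, ho, wo)
            x._accum(_col2im(gcols, (n, cin, h, wdt), k, stride, pad))
    out._backward = bw
    return out
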
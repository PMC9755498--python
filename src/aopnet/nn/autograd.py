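"""Minimal reverse-mode autograd over NumPy arrays.

Implements exactly the differentiable operations the dual-branch
segmentation network needs: elementwise arithmetic, ReLU/sigmoid,
channel softmax, 2-D convolution (im2col + GEMM), deformable 2-D
convolution with learned offsets, group normalization, 2x2 max pooling,
bilinear upsampling (separable interpolation matrices), channel
concatenation, and global summation.  All tensors are float32; feature
maps are laid out NCHW.

Gradient-graph construction can be switched off for inference via
:func:`no_grad`.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype != np.float64:  # float64 allowed for scalar loss stages
            arr = arr.astype(np.float32, copy=False)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _sum_to_shape(g, t.data.shape)
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _sum_to_shape(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == shape:
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ------------------------------------------------------------------ basics


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g)
        _accum(b, g)

    return _make(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g)
        _accum(b, -g)

    return _make(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _make(a.data * b.data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g / b.data)
        _accum(b, -g * a.data / (b.data * b.data))

    return _make(a.data / b.data, (a, b), bw)


def scalar_mul(a: Tensor, s: float) -> Tensor:
    def bw(g):
        _accum(a, g * s)

    return _make(a.data * s, (a,), bw)


def scalar_add(a: Tensor, s: float) -> Tensor:
    def bw(g):
        _accum(a, g)

    return _make(a.data + s, (a,), bw)


def tsum(a: Tensor) -> Tensor:
    """Global sum, accumulated in float64 (used by the scalar loss stage)."""

    def bw(g):
        _accum(a, np.broadcast_to(np.float32(g), a.data.shape))

    return _make(a.data.sum(dtype=np.float64), (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), bw)


def softmax_channels(a: Tensor) -> Tensor:
    """Softmax along axis 1 (channels) of an NCHW tensor."""
    m = a.data.max(axis=1, keepdims=True)
    e = np.exp(a.data - m)
    p = e / e.sum(axis=1, keepdims=True)

    def bw(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        _accum(a, p * (g - dot))

    return _make(p, (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


# ------------------------------------------------------------------ conv2d


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    if pad:
        xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
        xp[:, :, pad : pad + h, pad : pad + w] = x
        x = xp
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    dcols = dcols.reshape(n, c, k, k, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-size 2-D convolution, stride 1, odd kernel, zero padding.

    ``w`` has shape (out_c, in_c, k, k), ``b`` shape (out_c,).
    """
    n, c, h, wd = x.data.shape
    oc, ic, k, _ = w.data.shape
    pad = k // 2
    cols = _im2col(x.data, k, pad)
    wm = w.data.reshape(oc, ic * k * k)
    out = (wm @ cols).reshape(n, oc, h, wd) + b.data.reshape(1, oc, 1, 1)

    def bw(g):
        gm = g.reshape(n, oc, h * wd)
        _accum(b, g.sum(axis=(0, 2, 3)))
        gw = np.zeros((oc, ic * k * k), dtype=np.float32)
        for ni in range(n):
            gw += gm[ni] @ cols[ni].T
        _accum(w, gw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(wm.T[None], gm)
            _accum(x, _col2im(dcols, x.data.shape, k, pad))

    return _make(out, (x, w, b), bw)


# ------------------------------------------------------------- deformable


def deform_conv2d(x: Tensor, offsets: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3 deformable convolution, stride 1, same size.

    ``offsets`` is an NCHW tensor with 18 channels: for kernel tap ``k`` in
    row-major order, channel ``2k`` is the row (y) offset and ``2k + 1`` the
    column (x) offset.  Sampling is bilinear with zeros outside the input;
    offsets are shared across input channels, as in standard deformable
    convolution.
    """
    from ._deform_kernels import deform_gather, deform_scatter

    n, c, h, wd = x.data.shape
    oc = w.data.shape[0]
    hw = h * wd
    off = offsets.data.reshape(n, 9, 2, hw)
    cols = np.empty((n, c, 9, hw), dtype=np.float32)
    for ni in range(n):
        cols[ni] = deform_gather(
            x.data[ni], np.ascontiguousarray(off[ni, :, 0]), np.ascontiguousarray(off[ni, :, 1])
        )
    colsf = cols.reshape(n, c * 9, hw)
    wm = w.data.reshape(oc, c * 9)
    out = (wm @ colsf).reshape(n, oc, h, wd) + b.data.reshape(1, oc, 1, 1)

    def bw(g):
        gm = g.reshape(n, oc, hw)
        _accum(b, g.sum(axis=(0, 2, 3)))
        gw = np.zeros((oc, c * 9), dtype=np.float32)
        for ni in range(n):
            gw += gm[ni] @ colsf[ni].T
        _accum(w, gw.reshape(w.data.shape))
        dcols = np.matmul(wm.T[None], gm).reshape(n, c, 9, hw)
        need_dx = x.requires_grad
        need_doff = offsets.requires_grad
        dx = np.empty_like(x.data) if need_dx else None
        doff = np.empty((n, 9, 2, hw), dtype=np.float32) if need_doff else None
        for ni in range(n):
            dxi, doy, dox = deform_scatter(
                x.data[ni],
                np.ascontiguousarray(off[ni, :, 0]),
                np.ascontiguousarray(off[ni, :, 1]),
                np.ascontiguousarray(dcols[ni]),
                need_dx,
                need_doff,
            )
            if need_dx:
                dx[ni] = dxi
            if need_doff:
                doff[ni, :, 0] = doy
                doff[ni, :, 1] = dox
        if need_dx:
            _accum(x, dx)
        if need_doff:
            _accum(offsets, doff.reshape(offsets.data.shape))

    return _make(out, (x, offsets, w, b), bw)


# ------------------------------------------------------------- group norm


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    n, c, h, w = x.data.shape
    g = groups
    m = (c // g) * h * w
    xg = x.data.reshape(n, g, m)
    mean = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mean) * inv).reshape(n, c, h, w)
    out = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)

    def bw(gr):
        _accum(gamma, (gr * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, gr.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = (gr * gamma.data.reshape(1, c, 1, 1)).reshape(n, g, m)
            xh = xhat.reshape(n, g, m)
            t1 = dxhat.mean(axis=2, keepdims=True)
            t2 = (dxhat * xh).mean(axis=2, keepdims=True)
            dx = inv * (dxhat - t1 - xh * t2)
            _accum(x, dx.reshape(n, c, h, w))

    return _make(out, (x, gamma, beta), bw)


# --------------------------------------------------------------- pooling


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    ho, wo = h // 2, w // 2
    xr = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        _accum(x, dx)

    return _make(out, (x,), bw)


# -------------------------------------------------------------- upsample

_RESIZE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _linear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) bilinear interpolation matrix.

    Output sample i reads input coordinate ``(i + 0.5) * n_in / n_out - 0.5``
    (half-pixel alignment), clamped at the edges.
    """
    key = (n_out, n_in)
    if key in _RESIZE_CACHE:
        return _RESIZE_CACHE[key]
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(np.float32)
    R = np.zeros((n_out, n_in), dtype=np.float32)
    rows = np.arange(n_out)
    np.add.at(R, (rows, i0), 1.0 - f)
    np.add.at(R, (rows, i1), f)
    _RESIZE_CACHE[key] = R
    return R


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.data.shape
    Ry = _linear_matrix(h * factor, h)
    Rx = _linear_matrix(w * factor, w)
    out = np.matmul(np.matmul(Ry, x.data), Rx.T)

    def bw(g):
        _accum(x, np.matmul(np.matmul(Ry.T, g), Rx))

    return _make(out, (x,), bw)
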
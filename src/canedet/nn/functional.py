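"""Convolution, pooling and resizing primitives with autograd support.

Convolutions use im2col + BLAS matmul; grouped convolution (including
depthwise) reshapes into a leading group axis so one einsum serves every
group count.  Backward passes scatter-add through the same window views.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autograd import Tensor

__all__ = ["conv2d", "max_pool2d", "avg_pool2d", "upsample_nearest",
           "global_avg_pool", "conv_out_size"]


def conv_out_size(h: int, k: int, s: int, p: int) -> int:
    return (h + 2 * p - k) // s + 1


def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> contiguous (N, C, k, k, oh, ow) window view copy."""
    n, c, hp, wp = xp.shape
    sn, sc, sh, sw = xp.strides
    win = as_strided(xp, shape=(n, c, k, k, oh, ow),
                     strides=(sn, sc, sh, sw, sh * s, sw * s),
                     writeable=False)
    return np.ascontiguousarray(win)


def _col2im(gcols: np.ndarray, xp_shape, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    """Scatter-add (N, C, k, k, oh, ow) gradients back to (N, C, Hp, Wp)."""
    gxp = np.zeros(xp_shape, dtype=np.float32)
    for i in range(k):
        for j in range(k):
            gxp[:, :, i:i + oh * s:s, j:j + ow * s:s] += gcols[:, :, i, j]
    return gxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) of NCHW input.

    ``w`` has shape (C_out, C_in/groups, k, k); ``b`` broadcasts over the
    output channels.
    """
    xt = x if isinstance(x, Tensor) else Tensor(x)
    n, c, h, wd = xt.shape
    co, cig, k, k2 = w.shape
    assert k == k2, "square kernels only"
    assert c == cig * groups, f"channel mismatch: {c} vs {cig}x{groups}"
    oh = conv_out_size(h, k, stride, padding)
    ow = conv_out_size(wd, k, stride, padding)

    xp = np.pad(xt.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else xt.data
    cols = _im2col(xp, k, stride, oh, ow)            # (n, c, k, k, oh, ow)
    g = groups
    cg, cog = c // g, co // g
    colsg = cols.reshape(n, g, cg * k * k, oh * ow)
    wg = w.data.reshape(g, cog, cg * k * k)
    # (n, g, cog, oh*ow)
    out = np.einsum("gok,ngkl->ngol", wg, colsg, optimize=True)
    out = out.reshape(n, co, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)

    parents = (xt, w) if b is None else (xt, w, b)

    def bw(gout):
        gg = gout.reshape(n, g, cog, oh * ow)
        if w.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", gg, colsg, optimize=True)
            w._accum(gw.reshape(co, cig, k, k))
        if b is not None and b.requires_grad:
            b._accum(gout.sum(axis=(0, 2, 3)))
        if xt.requires_grad:
            gcolsg = np.einsum("gok,ngol->ngkl", wg, gg, optimize=True)
            gcols = gcolsg.reshape(n, c, k, k, oh, ow)
            gxp = _col2im(gcols, xp.shape, k, stride, oh, ow)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            xt._accum(gxp)

    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, k: int, stride: int | None = None, padding: int = 0) -> Tensor:
    """Max pooling; padded cells are -inf so they never win."""
    s = stride or k
    xt = x if isinstance(x, Tensor) else Tensor(x)
    n, c, h, w = xt.shape
    oh = conv_out_size(h, k, s, padding)
    ow = conv_out_size(w, k, s, padding)
    if padding:
        xp = np.full((n, c, h + 2 * padding, w + 2 * padding), -np.inf, dtype=np.float32)
        xp[:, :, padding:padding + h, padding:padding + w] = xt.data
    else:
        xp = xt.data
    cols = _im2col(xp, k, s, oh, ow).reshape(n, c, k * k, oh, ow)
    arg = cols.argmax(axis=2)
    out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]

    def bw(gout):
        if not xt.requires_grad:
            return
        gcols = np.zeros((n, c, k * k, oh, ow), dtype=np.float32)
        np.put_along_axis(gcols, arg[:, :, None], gout[:, :, None], axis=2)
        gxp = _col2im(gcols.reshape(n, c, k, k, oh, ow), xp.shape, k, s, oh, ow)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        xt._accum(gxp)

    return Tensor._make(out, (xt,), bw)


def avg_pool2d(x: Tensor, k: int, stride: int | None = None) -> Tensor:
    s = stride or k
    xt = x if isinstance(x, Tensor) else Tensor(x)
    n, c, h, w = xt.shape
    oh = conv_out_size(h, k, s, 0)
    ow = conv_out_size(w, k, s, 0)
    cols = _im2col(xt.data, k, s, oh, ow)
    out = cols.mean(axis=(2, 3))

    def bw(gout):
        if not xt.requires_grad:
            return
        gcols = np.broadcast_to(gout[:, :, None, None] / (k * k),
                                (n, c, k, k, oh, ow)).astype(np.float32)
        xt._accum(_col2im(gcols, xt.data.shape, k, s, oh, ow))

    return Tensor._make(out, (xt,), bw)


def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    xt = x if isinstance(x, Tensor) else Tensor(x)
    out = xt.data.repeat(scale, axis=-2).repeat(scale, axis=-1)

    def bw(gout):
        if not xt.requires_grad:
            return
        n, c, h, w = xt.shape
        g = gout.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
        xt._accum(g)

    return Tensor._make(out, (xt,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC11 mean over the spatial axes."""
    return x.mean(axis=(2, 3), keepdims=True)
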
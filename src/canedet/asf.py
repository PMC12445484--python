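"""Attentional scale-sequence fusion neck: SSFF, TFE and the attention add.

Stem nodes appear at wildly different scales depending on shooting
distance, and the stride-8/16/32 pyramid of the stock neck drops the
tiny ones.  Three ideas address this:

* **SSFF** (scale-sequence feature fusion) — project every pyramid level
  (including the stride-4 P2 tap) to a common width, resize to the fuse
  level, optionally blur into a Gaussian scale space, stack the levels
  along a new depth axis and fuse with a 1x1x1 3-D convolution followed
  by a depth max-pool.  The depth axis makes scale an explicit dimension
  the convolution can reason over.
* **TFE** (triple feature encoder) — encode a (finer, mid, coarser)
  triple at the mid resolution: the finer map is downsampled with a
  hybrid max+average pool, the coarser upsampled nearest, each projected
  to a common width, concatenated (3C) and convolved back to C.
* **AttnAdd** — a channel-attention gate over the sum of the SSFF product
  and a branch feature, so the fused scale evidence modulates rather
  than overwrites the branch.

All blocks are linear in their inputs when activations are disabled
(``act=None`` projections exist for the linearity tests).
"""

from __future__ import annotations

import numpy as np

from .nn import functional as F
from .nn.autograd import Tensor, concat, stack
from .nn.modules import (BatchNorm2d, Conv2d, ConvBN, LeakyReLU, Module,
                         ModuleList, PROFILER, Sequential)

__all__ = ["gaussian_kernel", "gaussian_smooth", "TFE", "SSFF", "AttnAdd",
           "hybrid_downsample"]


def gaussian_kernel(sigma: float, kernel_size: int) -> np.ndarray:
    """Normalized discrete 2-D Gaussian; always sums to 1."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd")
    r = kernel_size // 2
    ax = np.arange(-r, r + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx * xx + yy * yy) / (2.0 * sigma * sigma))
    return (k / k.sum()).astype(np.float32)


def gaussian_smooth(x, sigma: float, kernel_size: int = 5):
    """Same-padded Gaussian blur of a 2-D map or an NCHW tensor.

    Numpy arrays go through scipy-free direct convolution; tensors use a
    constant depthwise kernel so the scale space stays differentiable.
    """
    k = gaussian_kernel(sigma, kernel_size)
    if isinstance(x, np.ndarray) and x.ndim == 2:
        t = Tensor(x[None, None].astype(np.float32))
        w = Tensor(k[None, None])
        out = F.conv2d(t, w, padding=kernel_size // 2)
        return out.data[0, 0]
    c = x.shape[1]
    w = Tensor(np.broadcast_to(k, (c, 1, kernel_size, kernel_size)).copy())
    return F.conv2d(x, w, padding=kernel_size // 2, groups=c)


def hybrid_downsample(x, factor: int = 2):
    """Max + average pooled halving: keeps both peak and context evidence."""
    return F.max_pool2d(x, factor, factor) + F.avg_pool2d(x, factor, factor)


class TFE(Module):
    """Triple feature encoder at the mid level's resolution and width."""

    def __init__(self, c_large, c_mid, c_small, cout, act="silu"):
        super().__init__()
        self.proj_l = ConvBN(c_large, cout, 1, act=act)
        self.proj_m = ConvBN(c_mid, cout, 1, act=act)
        self.proj_s = ConvBN(c_small, cout, 1, act=act)
        self.fuse = ConvBN(3 * cout, cout, 1, act=act)

    def forward(self, f_large, f_mid, f_small):
        if f_large.shape[2] != 2 * f_mid.shape[2] or \
                f_small.shape[2] * 2 != f_mid.shape[2]:
            raise ValueError(
                "TFE expects a (2x, 1x, 0.5x) resolution triple, got "
                f"{f_large.shape[2:]} / {f_mid.shape[2:]} / {f_small.shape[2:]}")
        l = self.proj_l(hybrid_downsample(f_large))
        m = self.proj_m(f_mid)
        s = self.proj_s(F.upsample_nearest(f_small, 2))
        return self.fuse(concat([l, m, s], axis=1))


class _Fuse3D(Module):
    """1x1x1 3-D convolution + norm + LeakyReLU over a (level, H, W) stack.

    Implemented as a 1x1 2-D convolution over the depth-unrolled layout,
    which is arithmetically identical for a unit depth kernel.
    """

    def __init__(self, c):
        super().__init__()
        self.c = c
        self.conv = Conv2d(c, c, 1, bias=True)
        self.bn = BatchNorm2d(c)
        self.act = LeakyReLU(0.1)

    def forward(self, stacked):  # (n, c, d, h, w)
        n, c, d, h, w = stacked.shape
        flat = stacked.reshape(n, c, d * h, w)
        out = self.act(self.bn(self.conv(flat)))
        return out.reshape(n, out.shape[1], d, h, w)

    def _subtree_param_count(self, fused):
        raw = self.conv.weight.size + self.conv.cout + 2 * self.bn.c
        return self.conv.weight.size + self.conv.cout if fused else raw


class SSFF(Module):
    """Scale-sequence feature fusion over P2-P5 at the fuse level (P3).

    ``sigmas`` blur the coarser levels after resizing (None disables a
    level's blur); the depth max-pool collapses the scale axis back to a
    2-D map of the fuse level's width.
    """

    def __init__(self, in_channels, cout, sigmas=(None, 0.5, 1.0, 2.0),
                 kernel_size: int = 5, fuse_index: int = 1):
        super().__init__()
        if len(sigmas) != len(in_channels):
            raise ValueError("one sigma entry per pyramid level expected")
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.proj = ModuleList([ConvBN(c, cout, 1, act="silu")
                                for c in in_channels])
        self.fuse3d = _Fuse3D(cout)
        self.sigmas = tuple(sigmas)
        self.kernel_size = kernel_size
        self.fuse_index = fuse_index
        self.cout = cout

    def forward(self, feats):
        if len(feats) != len(self.proj):
            raise ValueError(f"expected {len(self.proj)} pyramid levels")
        target = feats[self.fuse_index].shape[2]
        resized = []
        for i, f in enumerate(feats):
            size = f.shape[2]
            if size > target:
                assert size % target == 0
                while f.shape[2] > target:
                    f = hybrid_downsample(f) * 0.5
            elif size < target:
                assert target % size == 0
                f = F.upsample_nearest(f, target // size)
            f = self.proj[i](f)
            if self.sigmas[i] is not None and not PROFILER.shape_only:
                f = gaussian_smooth(f, self.sigmas[i], self.kernel_size)
            resized.append(f)
        stacked = stack(resized, axis=2)           # (n, c, levels, h, w)
        fused = self.fuse3d(stacked)
        return fused.max(axis=2)                   # depth max-pool


class AttnAdd(Module):
    """Channel-gated residual combination of two same-shape maps."""

    def __init__(self, c, hidden):
        super().__init__()
        self.fc1 = Conv2d(c, hidden, 1, bias=True)
        self.fc2 = Conv2d(hidden, c, 1, bias=True)

    def forward(self, a, b):
        s = a + b
        g = self.fc2(self.fc1(F.global_avg_pool(s)).relu()).sigmoid()
        return s * g
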
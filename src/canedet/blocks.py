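"""Building blocks of the YOLO11-family detector graph.

These follow the eleventh-generation one-stage detector conventions:
``C3k2`` cross-stage blocks (optionally nesting two-bottleneck ``C3k``
units), ``SPPF`` pyramid pooling, the ``C2PSA`` attention stage, and the
decoupled anchor-free ``Detect`` head with distribution-focal box
regression and depthwise classification branches.  The structural
reproduction is exact: at nano scale with one class the fused parameter
total and the MACs-times-two GFLOPs match the published complexity
figures for this architecture digit for digit, which is the acceptance
surface for the whole graph.
"""

from __future__ import annotations

import numpy as np

from .nn.autograd import concat
from .nn.modules import (Conv2d, ConvBN, MaxPool2d, Module, ModuleList,
                         Parameter, Sequential)

__all__ = ["Bottleneck", "C3k", "C3k2", "SPPF", "Attention", "PSABlock",
           "C2PSA", "DWConvBN", "Detect", "dfl_expectation"]


def DWConvBN(c1, c2, k=3, stride=1):
    """Depthwise conv + BN + SiLU (groups = channel count)."""
    return ConvBN(c1, c2, k, stride, groups=c1)


class Bottleneck(Module):
    def __init__(self, c1, c2, shortcut=True, k=(3, 3), e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBN(c1, c_, k[0])
        self.cv2 = ConvBN(c_, c2, k[1])
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(Module):
    """CSP stage with two serial 3x3 bottlenecks on the transform path."""

    def __init__(self, c1, c2, n=2, shortcut=True, e=0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBN(c1, c_, 1)
        self.cv2 = ConvBN(c1, c_, 1)
        self.cv3 = ConvBN(2 * c_, c2, 1)
        self.m = Sequential(*[Bottleneck(c_, c_, shortcut, (3, 3), e=1.0)
                              for _ in range(n)])

    def forward(self, x):
        return self.cv3(concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3k2(Module):
    """Split-transform-merge block; ``c3k`` swaps the bottleneck for a C3k."""

    def __init__(self, c1, c2, n=1, c3k=False, e=0.5, shortcut=True):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = ConvBN(c1, 2 * self.c, 1)
        self.cv2 = ConvBN((2 + n) * self.c, c2, 1)
        self.m = ModuleList([
            C3k(self.c, self.c, 2, shortcut) if c3k
            else Bottleneck(self.c, self.c, shortcut, (3, 3), e=0.5)
            for _ in range(n)])
        # split widths of cv1's output; channel pruning may make them uneven
        self.split = [self.c, self.c]

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.split[0]]
        b = y[:, self.split[0]:]
        outs = [a, b]
        for m in self.m:
            outs.append(m(outs[-1]))
        return self.cv2(concat(outs, axis=1))


class SPPF(Module):
    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBN(c1, c_, 1)
        self.cv2 = ConvBN(c_ * 4, c2, 1)
        self.pool = MaxPool2d(k, stride=1, padding=k // 2)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.pool(y[-1]))
        return self.cv2(concat(y, axis=1))


class Attention(Module):
    """Multi-head self-attention with a depthwise positional branch."""

    def __init__(self, dim, num_heads, attn_ratio=0.5):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim ** -0.5
        h = dim + self.key_dim * num_heads * 2
        self.qkv = ConvBN(dim, h, 1, act=None)
        self.proj = ConvBN(dim, dim, 1, act=None)
        self.pe = ConvBN(dim, dim, 3, groups=dim, act=None)
        self.dim = dim

    def forward(self, x):
        n, c, hh, ww = x.shape
        L = hh * ww
        qkv = self.qkv(x).reshape(n, self.num_heads,
                                  self.key_dim * 2 + self.head_dim, L)
        q = qkv[:, :, : self.key_dim]
        k = qkv[:, :, self.key_dim: 2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim:]
        attn = (q.transpose((0, 1, 3, 2)) @ k) * self.scale
        attn = attn.softmax(axis=3)
        out = v @ attn.transpose((0, 1, 3, 2))
        out = out.reshape(n, c, hh, ww) + self.pe(v.reshape(n, c, hh, ww))
        return self.proj(out)


class PSABlock(Module):
    def __init__(self, c, num_heads):
        super().__init__()
        self.attn = Attention(c, num_heads)
        self.ffn = Sequential(ConvBN(c, c * 2, 1), ConvBN(c * 2, c, 1, act=None))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn(x)


class C2PSA(Module):
    def __init__(self, c1, c2, n=1):
        super().__init__()
        assert c1 == c2
        self.c = int(c1 * 0.5)
        self.cv1 = ConvBN(c1, 2 * self.c, 1)
        self.cv2 = ConvBN(2 * self.c, c1, 1)
        self.m = Sequential(*[PSABlock(self.c, self.c // 64) for _ in range(n)])
        self.split = [self.c, self.c]

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.split[0]]
        b = y[:, self.split[0]:]
        return self.cv2(concat([a, self.m(b)], axis=1))


def dfl_expectation(box_logits: np.ndarray, reg_max: int = 16) -> np.ndarray:
    """Distribution-focal decode: softmax over bins -> expected distance.

    ``box_logits`` is (..., 4*reg_max); returns (..., 4) expected l,t,r,b
    in grid units.
    """
    shape = box_logits.shape[:-1]
    z = box_logits.reshape(*shape, 4, reg_max)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    return (p * np.arange(reg_max, dtype=np.float32)).sum(axis=-1)


class Detect(Module):
    """Stock decoupled anchor-free head (box DFL branch + depthwise cls)."""

    def __init__(self, nc, ch, reg_max=16):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        self.nl = len(ch)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = ModuleList([
            Sequential(ConvBN(x, c2, 3), ConvBN(c2, c2, 3),
                       Conv2d(c2, 4 * reg_max, 1, bias=True))
            for x in ch])
        self.cv3 = ModuleList([
            Sequential(DWConvBN(x, x, 3), ConvBN(x, c3, 1),
                       DWConvBN(c3, c3, 3), ConvBN(c3, c3, 1),
                       Conv2d(c3, nc, 1, bias=True))
            for x in ch])
        # frozen projection of the distribution-focal decode; counted in
        # summaries like the reference implementation does
        self.dfl_proj = Parameter(np.arange(reg_max, dtype=np.float32),
                                  requires_grad=False)

    def forward(self, feats):
        return [concat([self.cv2[i](f), self.cv3[i](f)], axis=1)
                for i, f in enumerate(feats)]
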
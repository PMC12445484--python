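"""Lightweight shared detail-enhanced detection head (LSDECD).

The head runs one parameter-shared stem over all four pyramid levels.
Its convolutions are detail-enhanced (DEConv): five parallel 3x3
branches — one vanilla plus four *difference* convolutions whose kernels
are fixed linear rearrangements of their learnable parameters:

* CDC (central difference): the center tap carries minus the kernel sum,
  so constants are annihilated and local contrast is emphasized;
* ADC (angular difference): each tap minus its clockwise ring neighbour;
* HDC (horizontal difference): a 3-vector placed in the left column and
  subtracted in the right;
* VDC (vertical difference): the same along rows.

Because all five branches are 3x3 convolutions of the same input, their
sum collapses into a single kernel at deploy time (re-parameterization)
with exactly the parameter count of one vanilla convolution.

Normalization is GroupNorm — invariant to batch composition, which is
what makes small-batch training of a shared stem stable — and each
level applies a learnable scalar Scale to the regression output to
compensate for the shared stem seeing four different strides.
"""

from __future__ import annotations

import numpy as np

from .nn import functional as F
from .nn.autograd import Tensor, concat
from .nn.modules import (Conv2d, ConvGN, GroupNorm, Module, ModuleList,
                         PROFILER, Parameter, Scale, Sequential, SiLU)

__all__ = ["DEConv", "DEConvGN", "LSDECDHead"]

# clockwise ring permutation of a 3x3 kernel's flat indices (center fixed)
_ANGULAR_PERM = [3, 0, 1, 6, 4, 2, 7, 8, 5]
_CENTER_MASK = np.zeros((1, 1, 3, 3), dtype=np.float32)
_CENTER_MASK[0, 0, 1, 1] = 1.0


def _bound(cin, k=3):
    return 1.0 / np.sqrt(cin * k * k)


class DEConv(Module):
    """Five-branch detail-enhanced 3x3 convolution (same padding)."""

    def __init__(self, dim):
        super().__init__()
        self.dim = dim
        rng_b = _bound(dim)
        from .nn.modules import _rng
        r = _rng()
        def w(shape): return Parameter(r.uniform(-rng_b, rng_b, shape))
        self.w_vanilla = w((dim, dim, 3, 3))
        self.w_cd = w((dim, dim, 3, 3))
        self.w_ad = w((dim, dim, 3, 3))
        self.w_hd = w((dim, dim, 3))
        self.w_vd = w((dim, dim, 3))
        self.b_vanilla = w(dim)
        self.b_cd = w(dim)
        self.b_ad = w(dim)
        self.b_hd = w(dim)
        self.b_vd = w(dim)

    # -- kernel assembly (differentiable) -----------------------------

    def _kernels(self):
        d = self.dim
        zeros = Tensor(np.zeros((d, d, 3, 1), dtype=np.float32))
        zrow = Tensor(np.zeros((d, d, 1, 3), dtype=np.float32))

        k_v = self.w_vanilla
        k_cd = self.w_cd - Tensor(_CENTER_MASK) * self.w_cd.sum(
            axis=(2, 3), keepdims=True)
        flat = self.w_ad.reshape(d, d, 9)
        k_ad = self.w_ad - flat[:, :, _ANGULAR_PERM].reshape(d, d, 3, 3)
        col = self.w_hd.reshape(d, d, 3, 1)
        k_hd = concat([col, zeros, -col], axis=3)
        row = self.w_vd.reshape(d, d, 1, 3)
        k_vd = concat([row, zrow, -row], axis=2)
        return {"vanilla": (k_v, self.b_vanilla), "cdc": (k_cd, self.b_cd),
                "adc": (k_ad, self.b_ad), "hdc": (k_hd, self.b_hd),
                "vdc": (k_vd, self.b_vd)}

    def branch_outputs(self, x):
        """The five parallel branch outputs (training-path semantics)."""
        return {name: F.conv2d(x, k, b, padding=1)
                for name, (k, b) in self._kernels().items()}

    def forward(self, x):
        if PROFILER.active:
            n, c, h, w = x.shape
            # deploy-form cost: the five branches fold into one 3x3 conv
            PROFILER.macs += self.dim * self.dim * 9 * h * w * n
            if getattr(self, "_hw_token", -1) != PROFILER.token:
                self.last_out_hw = 0
                self._hw_token = PROFILER.token
            self.last_out_hw += h * w
            if PROFILER.shape_only:
                return Tensor(np.zeros((n, self.dim, h, w), dtype=np.float32))
        outs = self.branch_outputs(x)
        total = None
        for o in outs.values():
            total = o if total is None else total + o
        return total

    def reparameterize(self):
        """Summed 3x3 kernel and bias equivalent to the five branches."""
        ks = self._kernels()
        k = sum(kk.data for kk, _ in ks.values())
        b = sum(bb.data for _, bb in ks.values())
        return k, b

    def as_deploy_conv(self) -> Conv2d:
        conv = Conv2d(self.dim, self.dim, 3, bias=True)
        k, b = self.reparameterize()
        conv.weight.data[...] = k
        conv.bias.data[...] = b
        return conv


class DEConvGN(Module):
    """DEConv + GroupNorm + SiLU: one stem stage of the shared head."""

    def __init__(self, dim, gn_groups=16):
        super().__init__()
        self.deconv = DEConv(dim)
        self.gn = GroupNorm(int(np.gcd(gn_groups, dim)), dim)
        self.act = SiLU()

    def forward(self, x):
        return self.act(self.gn(self.deconv(x)))


class LSDECDHead(Module):
    """Parameter-shared detail-enhanced head over four pyramid levels.

    Per level: a 1x1 ConvGN lateral to the shared width, then the shared
    two-stage DEConv stem, then shared 1x1 box (4*reg_max channels, DFL
    parametrization) and class projections; a per-level Scale multiplies
    the regression logits.
    """

    def __init__(self, nc, ch, hidc, reg_max=16, gn_groups=16,
                 scale_init=1.0):
        super().__init__()
        if hidc <= 0 or hidc % gn_groups:
            raise ValueError("shared width must be divisible by gn_groups")
        self.nc = nc
        self.reg_max = reg_max
        self.nl = len(ch)
        self.hidc = hidc
        self.lateral = ModuleList([ConvGN(x, hidc, 1, gn_groups=gn_groups)
                                   for x in ch])
        self.share = Sequential(DEConvGN(hidc, gn_groups),
                                DEConvGN(hidc, gn_groups))
        self.cv_box = Conv2d(hidc, 4 * reg_max, 1, bias=True)
        self.cv_cls = Conv2d(hidc, nc, 1, bias=True)
        self.scales = ModuleList([Scale(scale_init) for _ in ch])
        self.dfl_proj = Parameter(np.arange(reg_max, dtype=np.float32),
                                  requires_grad=False)

    def forward(self, feats):
        if len(feats) != self.nl:
            raise ValueError(f"expected {self.nl} levels, got {len(feats)}")
        outs = []
        for i, f in enumerate(feats):
            t = self.share(self.lateral[i](f))
            box = self.scales[i](self.cv_box(t))
            cls = self.cv_cls(t)
            outs.append(concat([box, cls], axis=1))
        return outs
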
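"""Module system and the standard convolutional blocks.

Mirrors the familiar layer conventions of modern one-stage detectors:
``ConvBN`` is conv + batch norm + SiLU (bias-free conv, BN foldable at
deploy time), ``ConvGN`` swaps the norm for group normalization (batch-
composition independent — the right choice for small-batch training and
shared heads).  Weight initialization follows the usual fan-in uniform
scheme; a module-level RNG keeps builds reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .autograd import Tensor

__all__ = ["seed_rng", "Parameter", "Module", "ModuleList", "Sequential",
           "Conv2d", "BatchNorm2d", "GroupNorm", "ConvBN", "ConvGN",
           "SiLU", "LeakyReLU", "Identity", "Upsample", "MaxPool2d", "Scale",
           "PROFILER"]

_RNG = [np.random.default_rng(0)]


def seed_rng(seed: int):
    """Reseed the initializer RNG (call before building a model)."""
    _RNG[0] = np.random.default_rng(seed)


def _rng() -> np.random.Generator:
    return _RNG[0]


def Parameter(data, requires_grad: bool = True) -> Tensor:
    t = Tensor(np.asarray(data, dtype=np.float32), requires_grad=requires_grad)
    return t


class _Profiler:
    """Global MAC counter; ``shape_only`` skips the arithmetic entirely."""

    def __init__(self):
        self.active = False
        self.shape_only = False
        self.macs = 0
        self.token = 0  # bumps per profile run; convs reset their area sums

    def reset(self):
        self.macs = 0
        self.token += 1


PROFILER = _Profiler()


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_mods", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for n, m in self._mods.items():
            sub = f"{prefix}.{n}" if prefix else n
            yield from m.named_modules(sub)

    def modules(self):
        for _, m in self.named_modules():
            yield m

    def named_parameters(self, prefix: str = ""):
        for pn, p in self._params.items():
            yield (f"{prefix}.{pn}" if prefix else pn), p
        for mn, m in self._mods.items():
            sub = f"{prefix}.{mn}" if prefix else mn
            yield from m.named_parameters(sub)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    _buffer_names: tuple = ()  # non-trainable state (e.g. BN running stats)

    def named_buffers(self, prefix: str = ""):
        for bn in self._buffer_names:
            yield (f"{prefix}.{bn}" if prefix else bn), getattr(self, bn)
        for mn, m in self._mods.items():
            sub = f"{prefix}.{mn}" if prefix else mn
            yield from m.named_buffers(sub)

    def state_dict(self) -> dict:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        out.update({n: b.copy() for n, b in self.named_buffers()})
        return out

    def load_state_dict(self, sd: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(sd)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)[:5]} ...")
        for n, p in own.items():
            if p.data.shape != sd[n].shape:
                raise ValueError(f"shape mismatch for {n}: "
                                 f"{p.data.shape} vs {sd[n].shape}")
            p.data[...] = sd[n]
        for n, _ in self.named_buffers():
            if n in sd:
                self._set_buffer(n, sd[n])

    def _set_buffer(self, dotted: str, value):
        parts = dotted.split(".")
        mod = self
        for p in parts[:-1]:
            mod = mod._mods[p]
        getattr(mod, parts[-1])[...] = value

    def train(self, flag: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)

    def forward(self, *args, **kw):  # pragma: no cover - abstract
        raise NotImplementedError

    # -- complexity accounting ---------------------------------------

    def param_count(self, fused: bool = True) -> int:
        """Total parameter scalars, optionally under conv+BN fusion.

        Fusion is the deploy-time fold of a BatchNorm into its preceding
        bias-free conv (weights unchanged, one bias per output channel);
        complexity tables for detectors are conventionally quoted in this
        fused form.
        """
        return self._subtree_param_count(fused)

    def _subtree_param_count(self, fused: bool) -> int:
        total = sum(p.size for p in self._params.values())
        for m in self._mods.values():
            total += m._subtree_param_count(fused)
        return total


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        name = str(len(self._list))
        self._list.append(m)
        self._mods[name] = m
        object.__setattr__(self, name, m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            self._mods[str(i)] = m
            object.__setattr__(self, str(i), m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Conv2d(Module):
    """Plain convolution with optional bias (no norm, no activation)."""

    def __init__(self, cin, cout, k, stride=1, padding=None, groups=1,
                 bias=True, trainable=True):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (cin // groups) * k * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(
            _rng().uniform(-bound, bound, (cout, cin // groups, k, k)),
            requires_grad=trainable)
        self.bias = Parameter(_rng().uniform(-bound, bound, cout),
                              requires_grad=trainable) if bias else None

    def forward(self, x):
        n, c, h, w = x.shape
        oh = F.conv_out_size(h, self.k, self.stride, self.padding)
        ow = F.conv_out_size(w, self.k, self.stride, self.padding)
        if PROFILER.active:
            PROFILER.macs += (self.cout * (self.cin // self.groups)
                              * self.k * self.k * oh * ow * n)
            if getattr(self, "_hw_token", -1) != PROFILER.token:
                self.last_out_hw = 0
                self._hw_token = PROFILER.token
            self.last_out_hw += oh * ow
            if PROFILER.shape_only:
                return Tensor(np.zeros((n, self.cout, oh, ow), dtype=np.float32))
        return F.conv2d(x, self.weight, self.bias, self.stride,
                        self.padding, self.groups)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, c, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        c = self.c
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class GroupNorm(Module):
    """Normalization over channel groups: independent of batch composition."""

    def __init__(self, groups, c, eps: float = 1e-5):
        super().__init__()
        if c % groups:
            raise ValueError(f"channels {c} not divisible by groups {groups}")
        self.groups, self.c, self.eps = groups, c, eps
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))

    def forward(self, x):
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        xhat = ((xg - mu) / ((var + self.eps) ** 0.5)).reshape(n, c, h, w)
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class LeakyReLU(Module):
    def __init__(self, slope=0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Identity(Module):
    def forward(self, x):
        return x


class Upsample(Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return F.upsample_nearest(x, self.scale)


class MaxPool2d(Module):
    def __init__(self, k, stride=None, padding=0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride or k, padding

    def forward(self, x):
        return F.max_pool2d(x, self.k, self.stride, self.padding)


class Scale(Module):
    """Learnable scalar gain (per-level magnitude correction in the head)."""

    def __init__(self, init: float = 1.0):
        super().__init__()
        self.gain = Parameter(np.array([init]))

    def forward(self, x):
        return x * self.gain.reshape(1, 1, 1, 1)


class ConvBN(Module):
    """conv (no bias) + BatchNorm + activation; BN folds away at deploy.

    The fused parameter count is ``weight + cout`` (the bias the fold
    creates), which is the convention complexity tables are quoted in.
    """

    def __init__(self, cin, cout, k=1, stride=1, padding=None, groups=1,
                 act: str | None = "silu"):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = {"silu": SiLU(), "lrelu": LeakyReLU(),
                    None: Identity()}[act]

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))

    def _subtree_param_count(self, fused: bool) -> int:
        raw = self.conv.weight.size + 2 * self.bn.c
        return self.conv.weight.size + self.bn.c if fused else raw


class ConvGN(Module):
    """conv (no bias) + GroupNorm + SiLU; nothing to fold at deploy."""

    def __init__(self, cin, cout, k=1, stride=1, padding=None, gn_groups=16):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, bias=False)
        self.gn = GroupNorm(math.gcd(gn_groups, cout), cout)
        self.act = SiLU()

    def forward(self, x):
        return self.act(self.gn(self.conv(x)))
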
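"""Model assembly: baseline YOLO11n (nc=1), the ASF-P2 intermediate, and
the improved detector (ASF-P2 neck + shared detail-enhanced head).

Complexity accounting is part of the contract: parameter totals are
reported in deploy (conv+BN fused) form and GFLOPs with the MACs-times-two
convention, the same conventions detector complexity tables are printed
in.  The improved variants' channel widths are frozen package defaults;
``scripts/derive_widths.py`` documents how they were derived from the
printed complexity budget.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import yaml

from .asf import SSFF, TFE, AttnAdd
from .blocks import C2PSA, C3k2, Detect, SPPF
from .lsdecd import LSDECDHead
from .nn.autograd import concat
from .nn.modules import ConvBN, Module, Upsample, seed_rng
from .nn.profile import count_parameters, gflops

__all__ = ["NeckConfig", "HeadConfig", "ModelSpec", "ComplexityReport",
           "Backbone", "ASFP2Neck", "YOLO11nBaseline", "StemNodeNet",
           "build_model", "complexity_report", "VARIANTS"]

VARIANTS = ("yolo11n", "yolo11-asf-p2", "ours")


@dataclass(frozen=True)
class NeckConfig:
    """Channel plan of the ASF-P2 neck (defaults match the printed
    complexity budget; see scripts/derive_widths.py)."""

    w4: int = 112          # top-down P4 branch width
    w3: int = 32           # top-down P3 branch width
    w2: int = 30           # P2 (stride-4) branch width
    b3: int = 69           # bottom-up P3 output width (= SSFF width)
    b4: int = 161          # bottom-up P4 output width
    b5: int = 209          # bottom-up P5 output width
    attn_hidden: int = 15  # channel-attention bottleneck of the add block
    c3k_n4: bool = False
    c3k_n4b: bool = False
    c3k_n5b: bool = False
    sigmas: tuple = (None, 0.5, 1.0, 2.0)

    @property
    def out_channels(self) -> tuple:
        return (self.w2, self.b3, self.b4, self.b5)


@dataclass(frozen=True)
class HeadConfig:
    """Shared-head plan: four levels, single class, DFL regression."""

    num_classes: int = 1
    hidc: int = 64         # shared stem width
    gn_groups: int = 16
    reg_max: int = 16
    scale_init: float = 1.0


@dataclass(frozen=True)
class ModelSpec:
    variant: str = "ours"
    num_classes: int = 1
    input_size: int = 640
    seed: int = 0
    neck: NeckConfig = field(default_factory=NeckConfig)
    head: HeadConfig = field(default_factory=HeadConfig)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    def to_yaml(self) -> str:
        buf = io.StringIO()
        yaml.safe_dump({"variant": self.variant, "nc": self.num_classes,
                        "input_size": self.input_size,
                        "neck": asdict(self.neck), "head": asdict(self.head)},
                       buf, sort_keys=False)
        return buf.getvalue()


@dataclass
class ComplexityReport:
    parameters: int
    gflops: float
    size_mb_fp16: float
    size_mb_fp32: float

    def as_dict(self):
        return asdict(self)


class Backbone(Module):
    """YOLO11 nano backbone exposing the P2/P3/P4/P5 taps."""

    OUT_CHANNELS = (64, 128, 128, 256)

    def __init__(self):
        super().__init__()
        self.l0 = ConvBN(3, 16, 3, 2)
        self.l1 = ConvBN(16, 32, 3, 2)
        self.l2 = C3k2(32, 64, e=0.25)
        self.l3 = ConvBN(64, 64, 3, 2)
        self.l4 = C3k2(64, 128, e=0.25)
        self.l5 = ConvBN(128, 128, 3, 2)
        self.l6 = C3k2(128, 128, c3k=True)
        self.l7 = ConvBN(128, 256, 3, 2)
        self.l8 = C3k2(256, 256, c3k=True)
        self.l9 = SPPF(256, 256, 5)
        self.l10 = C2PSA(256, 256)

    def forward(self, x):
        p2 = self.l2(self.l1(self.l0(x)))
        p3 = self.l4(self.l3(p2))
        p4 = self.l6(self.l5(p3))
        p5 = self.l10(self.l9(self.l8(self.l7(p4))))
        return p2, p3, p4, p5


class YOLO11nBaseline(Module):
    """Stock three-scale YOLO11n with a single output class."""

    def __init__(self, nc=1):
        super().__init__()
        self.backbone = Backbone()
        self.up = Upsample(2)
        self.n13 = C3k2(384, 128)
        self.n16 = C3k2(256, 64)
        self.d17 = ConvBN(64, 64, 3, 2)
        self.n19 = C3k2(192, 128)
        self.d20 = ConvBN(128, 128, 3, 2)
        self.n22 = C3k2(384, 256, c3k=True)
        self.detect = Detect(nc, (64, 128, 256))
        self.strides = (8, 16, 32)

    def forward(self, x):
        _, p3, p4, p5 = self.backbone(x)
        t13 = self.n13(concat([self.up(p5), p4], axis=1))
        t16 = self.n16(concat([self.up(t13), p3], axis=1))
        t19 = self.n19(concat([self.d17(t16), t13], axis=1))
        t22 = self.n22(concat([self.d20(t19), p5], axis=1))
        return self.detect([t16, t19, t22])


class ASFP2Neck(Module):
    """PANet over P2-P5 with TFE encoders on the top-down path and the
    SSFF scale-sequence product gated into the bottom-up P3 branch."""

    def __init__(self, cfg: NeckConfig, in_channels=Backbone.OUT_CHANNELS):
        super().__init__()
        c2, c3, c4, c5 = in_channels
        self.cfg = cfg
        self.up = Upsample(2)
        self.tfe4 = TFE(c3, c4, c5, cfg.w4)
        self.n4 = C3k2(cfg.w4, cfg.w4, c3k=cfg.c3k_n4)
        self.tfe3 = TFE(c2, c3, cfg.w4, cfg.w3)
        self.n3 = C3k2(cfg.w3, cfg.w3)
        self.n2 = C3k2(cfg.w3 + c2, cfg.w2)
        self.d2 = ConvBN(cfg.w2, cfg.w2, 3, 2)
        self.n3b = C3k2(cfg.w2 + cfg.w3, cfg.b3)
        self.ssff = SSFF(in_channels, cfg.b3, cfg.sigmas)
        self.add3 = AttnAdd(cfg.b3, cfg.attn_hidden)
        self.d3 = ConvBN(cfg.b3, cfg.b3, 3, 2)
        self.n4b = C3k2(cfg.b3 + cfg.w4, cfg.b4, c3k=cfg.c3k_n4b)
        self.d4 = ConvBN(cfg.b4, cfg.b4, 3, 2)
        self.n5b = C3k2(cfg.b4 + c5, cfg.b5, c3k=cfg.c3k_n5b)

    def forward(self, p2, p3, p4, p5):
        t4 = self.n4(self.tfe4(p3, p4, p5))
        t3 = self.n3(self.tfe3(p2, p3, t4))
        t2 = self.n2(concat([self.up(t3), p2], axis=1))
        u3 = self.n3b(concat([self.d2(t2), t3], axis=1))
        u3 = self.add3(u3, self.ssff([p2, p3, p4, p5]))
        u4 = self.n4b(concat([self.d3(u3), t4], axis=1))
        u5 = self.n5b(concat([self.d4(u4), p5], axis=1))
        return t2, u3, u4, u5


class StemNodeNet(Module):
    """Backbone + ASF-P2 neck + either the stock four-scale head
    (variant ``yolo11-asf-p2``) or the shared LSDECD head (``ours``)."""

    def __init__(self, variant="ours", nc=1, neck_cfg: NeckConfig | None = None,
                 head_cfg: HeadConfig | None = None):
        super().__init__()
        neck_cfg = neck_cfg or NeckConfig()
        head_cfg = head_cfg or HeadConfig(num_classes=nc)
        self.backbone = Backbone()
        self.neck = ASFP2Neck(neck_cfg)
        ch = neck_cfg.out_channels
        if variant == "ours":
            self.head = LSDECDHead(nc, ch, head_cfg.hidc, head_cfg.reg_max,
                                   head_cfg.gn_groups, head_cfg.scale_init)
        else:
            self.head = Detect(nc, ch, head_cfg.reg_max)
        self.variant = variant
        self.strides = (4, 8, 16, 32)

    def forward(self, x):
        p2, p3, p4, p5 = self.backbone(x)
        return self.head(list(self.neck(p2, p3, p4, p5)))


def build_model(spec: ModelSpec | str) -> Module:
    """Instantiate a variant with reproducible initialization."""
    if isinstance(spec, str):
        spec = ModelSpec(variant=spec)
    seed_rng(spec.seed)
    if spec.variant == "yolo11n":
        return YOLO11nBaseline(spec.num_classes)
    return StemNodeNet(spec.variant, spec.num_classes, spec.neck, spec.head)


def complexity_report(net: Module, input_size: int = 640) -> ComplexityReport:
    p = count_parameters(net, fused=True)
    return ComplexityReport(parameters=p,
                            gflops=round(gflops(net, input_size), 1),
                            size_mb_fp16=round(p * 2 / 1e6, 1),
                            size_mb_fp32=round(p * 4 / 1e6, 1))
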
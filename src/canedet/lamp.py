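"""Layer-adaptive magnitude (LAMP) scoring and structured channel pruning.

LAMP rescales squared weight magnitudes by the tail mass of their own
layer: with a layer's values sorted ascending, ``score[i] = W[i]^2 /
sum_{j>=i} W[j]^2``.  The largest value in every layer scores exactly 1,
so scores are comparable *across* layers without any per-layer pruning
ratio — the layer-adaptive part.  Applied to the vector of per-channel
l1 magnitudes of each coupled channel group, it ranks channels globally.

Structured pruning must respect channel coupling: residual adds tie the
channels of their operands, concatenations map producer channels to
consumer offsets, depthwise convolutions tie input to output, and a
shared head stem ties all four lateral projections together.  The tracer
below walks the model graph (the same wiring the forward pass uses) and
produces the coupled groups; pruning then physically slices weights, so
the pruned network really is smaller — its FLOP count is re-measured,
not estimated.

Protected groups (attention interiors, the shared head stem, all
detection output convolutions) are scored but never pruned; the head
keeps its channels to preserve localization accuracy, and the fusion
layers absorb almost all of the sparsity, which is exactly the pattern
channel pruning of this detector family shows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .asf import SSFF, TFE, AttnAdd
from .blocks import (Attention, Bottleneck, C2PSA, C3k, C3k2, Detect,
                     PSABlock, SPPF)
from .lsdecd import DEConv, LSDECDHead
from .nn.modules import (BatchNorm2d, Conv2d, ConvBN, ConvGN, GroupNorm,
                         MaxPool2d, Module, Scale, Sequential, SiLU, Upsample)
from .nn.profile import profile_macs
from .assembly import ASFP2Neck, Backbone, StemNodeNet, YOLO11nBaseline

__all__ = ["LayerWeightView", "PruneSchedule", "PruneReport", "Group",
           "lamp_score", "trace_groups", "channel_importance", "prune"]


# ---------------------------------------------------------------------------
# LAMP score
# ---------------------------------------------------------------------------

@dataclass
class LayerWeightView:
    """Flattened magnitude view of one layer, sorted ascending."""

    layer_id: str
    magnitudes: np.ndarray     # |W| sorted ascending
    index_map: np.ndarray      # position in the original flat tensor

    @classmethod
    def from_tensor(cls, layer_id: str, w: np.ndarray) -> "LayerWeightView":
        flat = np.abs(np.asarray(w, dtype=np.float64)).ravel()
        order = np.argsort(flat, kind="stable")
        return cls(layer_id, flat[order], order)


def lamp_score(view) -> np.ndarray:
    """LAMP scores in the view's (ascending) order.

    ``score[i] = m[i]^2 / sum_{j >= i} m[j]^2``; the top magnitude scores
    exactly 1 and larger magnitudes always outrank smaller ones within a
    layer.  An all-zero layer is defined as all-zero scores (warned).
    """
    if isinstance(view, LayerWeightView):
        m = view.magnitudes
    else:
        m = np.sort(np.abs(np.asarray(view, dtype=np.float64)).ravel())
    if m.size == 0:
        raise ValueError("empty weight view")
    sq = m * m
    tail = np.cumsum(sq[::-1])[::-1]
    if tail[0] == 0.0:
        warnings.warn("all-zero layer: LAMP scores defined as 0", stacklevel=2)
        return np.zeros_like(sq)
    return sq / tail


# ---------------------------------------------------------------------------
# coupled channel groups
# ---------------------------------------------------------------------------

class Group:
    """A set of channel slots that must be pruned together."""

    def __init__(self, width: int, name: str = ""):
        self.width = width
        self.name = name
        self.producers: list = []   # (Conv2d, out_offset)
        self.consumers: list = []   # (Conv2d, in_offset)
        self.dw: list = []          # depthwise convs tied to this group
        self.norms: list = []       # (BatchNorm2d | GroupNorm, offset)
        self.split_refs: list = []  # (module_with_.split, index)
        self.protected = False
        self._parent: "Group" | None = None
        # live bookkeeping during the pruning loop
        self.keep = np.ones(width, dtype=bool)

    def find(self) -> "Group":
        g = self
        while g._parent is not None:
            g = g._parent
        if g is not self:
            self._parent = g
        return g

    def merge(self, other: "Group") -> "Group":
        a, b = self.find(), other.find()
        if a is b:
            return a
        if a.width != b.width:
            raise ValueError(
                f"cannot couple groups of widths {a.width} and {b.width} "
                f"({a.name!r} vs {b.name!r})")
        a.producers += b.producers
        a.consumers += b.consumers
        a.dw += b.dw
        a.norms += b.norms
        a.split_refs += b.split_refs
        a.protected = a.protected or b.protected
        b._parent = a
        return a

    @property
    def live(self) -> int:
        return int(self.find().keep.sum())


def _segs(x):
    """Normalize a group or a list of (group, width) segments."""
    if isinstance(x, Group):
        return [(x.find(), x.find().width)]
    return [(g.find(), w) for g, w in x]


def _consume(conv: Conv2d, gin):
    off = 0
    for g, w in _segs(gin):
        g.consumers.append((conv, off))
        off += w
    if off != conv.cin:
        raise ValueError(f"consumer width mismatch: {off} vs {conv.cin}")


class _Tracer:
    def __init__(self):
        self.groups: list[Group] = []
        self._protect_depth = 0
        self._n = 0

    def new(self, width, name="") -> Group:
        g = Group(width, name or f"g{self._n}")
        self._n += 1
        g.protected = self._protect_depth > 0
        self.groups.append(g)
        return g

    # ---- per-module rules -------------------------------------------

    def convbn(self, m: ConvBN, gin, name=""):
        if m.conv.groups > 1:  # depthwise
            (g, w), = _segs(gin)
            if m.conv.groups != m.conv.cin or m.conv.cin != m.conv.cout:
                raise NotImplementedError("only full depthwise groups supported")
            g.dw.append(m.conv)
            g.norms.append((m.bn, 0))
            if self._protect_depth:
                g.protected = True
            return g
        _consume(m.conv, gin)
        gout = self.new(m.conv.cout, name)
        gout.producers.append((m.conv, 0))
        gout.norms.append((m.bn, 0))
        return gout

    def convgn(self, m: ConvGN, gin, name=""):
        _consume(m.conv, gin)
        gout = self.new(m.conv.cout, name)
        gout.producers.append((m.conv, 0))
        gout.norms.append((m.gn, 0))
        return gout

    def conv2d(self, m: Conv2d, gin, name=""):
        _consume(m, gin)
        gout = self.new(m.cout, name)
        gout.producers.append((m, 0))
        return gout

    def bottleneck(self, m: Bottleneck, gin):
        g1 = self.convbn(m.cv1, gin)
        g2 = self.convbn(m.cv2, g1)
        if m.add:
            (g, _), = _segs(gin)
            return g.merge(g2)
        return g2

    def c3k(self, m: C3k, gin):
        ga = self.convbn(m.cv1, gin)
        gb = self.convbn(m.cv2, gin)
        cur = ga
        for b in m.m:
            cur = self.bottleneck(b, cur)
        return self.convbn(m.cv3, [(cur, cur.find().width), (gb, gb.width)])

    def c3k2(self, m: C3k2, gin):
        _consume(m.cv1.conv, gin)
        c = m.split[0]
        ga = self.new(c, "c3k2.a")
        gb = self.new(m.split[1], "c3k2.b")
        ga.producers.append((m.cv1.conv, 0))
        gb.producers.append((m.cv1.conv, c))
        ga.norms.append((m.cv1.bn, 0))
        gb.norms.append((m.cv1.bn, c))
        ga.split_refs.append((m, 0))
        gb.split_refs.append((m, 1))
        outs = [ga, gb]
        for sub in m.m:
            if isinstance(sub, C3k):
                outs.append(self.c3k(sub, outs[-1]))
            else:
                outs.append(self.bottleneck(sub, outs[-1]))
        seen_pairs = [(g.find(), g.find().width) for g in outs]
        return self.convbn(m.cv2, seen_pairs)

    def sppf(self, m: SPPF, gin):
        g1 = self.convbn(m.cv1, gin)
        return self.convbn(m.cv2, [(g1, g1.width)] * 4)

    def attention(self, m: Attention, gin):
        self._protect_depth += 1
        try:
            (g, _), = _segs(gin)
            g.protected = True
            gq = self.convbn(m.qkv, g)
            gq.protected = True
            # positional branch: depthwise on the value slice; the value
            # channels coincide with the block width, keep it all frozen
            g.dw.append(m.pe.conv)
            g.norms.append((m.pe.bn, 0))
            gp = self.convbn(m.proj, g)
            gp.protected = True
            return g.merge(gp)
        finally:
            self._protect_depth -= 1

    def psablock(self, m: PSABlock, gin):
        (g, _), = _segs(gin)
        g.protected = True
        self.attention(m.attn, g)
        self._protect_depth += 1
        try:
            h = self.convbn(m.ffn[0], g)
            o = self.convbn(m.ffn[1], h)
            g.merge(o)
        finally:
            self._protect_depth -= 1
        return g

    def c2psa(self, m: C2PSA, gin):
        _consume(m.cv1.conv, gin)
        c = m.split[0]
        ga = self.new(c, "c2psa.a")
        gb = self.new(m.split[1], "c2psa.b")
        ga.producers.append((m.cv1.conv, 0))
        gb.producers.append((m.cv1.conv, c))
        ga.norms.append((m.cv1.bn, 0))
        gb.norms.append((m.cv1.bn, c))
        ga.split_refs.append((m, 0))
        gb.split_refs.append((m, 1))
        gb.protected = True
        cur = gb
        for blk in m.m:
            cur = self.psablock(blk, cur)
        return self.convbn(m.cv2, [(ga, ga.width), (cur, cur.find().width)])

    def tfe(self, m: TFE, g_l, g_m, g_s):
        a = self.convbn(m.proj_l, g_l)
        b = self.convbn(m.proj_m, g_m)
        c = self.convbn(m.proj_s, g_s)
        return self.convbn(m.fuse, [(a, a.width), (b, b.width), (c, c.width)])

    def ssff(self, m: SSFF, gins):
        projs = [self.convbn(p, g) for p, g in zip(m.proj, gins)]
        base = projs[0]
        for p in projs[1:]:
            base = base.merge(p)  # depth stack aligns channels level-wise
        _consume(m.fuse3d.conv, base)
        gout = self.new(m.fuse3d.c, "ssff.fuse")
        gout.producers.append((m.fuse3d.conv, 0))
        gout.norms.append((m.fuse3d.bn, 0))
        return gout

    def attnadd(self, m: AttnAdd, ga, gb):
        s = ga.find().merge(gb.find())
        hid = self.conv2d(m.fc1, s, "attnadd.hidden")
        gate = self.conv2d(m.fc2, hid)
        return s.merge(gate)

    def detect(self, m: Detect, gins):
        for i, gin in enumerate(gins):
            g1 = self.convbn(m.cv2[i][0], gin)
            g2 = self.convbn(m.cv2[i][1], g1)
            out = self.conv2d(m.cv2[i][2], g2, f"detect.box{i}")
            out.protected = True
            g = self.convbn(m.cv3[i][0], gin)       # depthwise: same group
            g3 = self.convbn(m.cv3[i][1], g)
            g3 = self.convbn(m.cv3[i][2], g3)       # depthwise on c3
            g4 = self.convbn(m.cv3[i][3], g3)
            outc = self.conv2d(m.cv3[i][4], g4, f"detect.cls{i}")
            outc.protected = True

    def lsdecd(self, m: LSDECDHead, gins):
        self._protect_depth += 1
        try:
            stem = None
            for lat, gin in zip(m.lateral, gins):
                self._protect_depth -= 1
                _consume(lat.conv, gin)     # neck outputs stay prunable
                self._protect_depth += 1
                g = self.new(lat.conv.cout, "lsdecd.stem")
                g.protected = True
                g.producers.append((lat.conv, 0))
                g.norms.append((lat.gn, 0))
                stem = g if stem is None else stem.merge(g)
            cur = stem
            for stage in m.share:
                # the DEConv stages keep the shared width; they are frozen
                # with the stem, so only the norm needs group membership
                cur.norms.append((stage.gn, 0))
            for cv in (m.cv_box, m.cv_cls):
                out = self.conv2d(cv, cur)
                out.protected = True
        finally:
            self._protect_depth -= 1

    # ---- whole-model wiring -----------------------------------------

    def backbone(self, bb: Backbone, gin):
        g = self.convbn(bb.l0, gin)
        g = self.convbn(bb.l1, g)
        p2 = self.c3k2(bb.l2, g)
        g = self.convbn(bb.l3, p2)
        p3 = self.c3k2(bb.l4, g)
        g = self.convbn(bb.l5, p3)
        p4 = self.c3k2(bb.l6, g)
        g = self.convbn(bb.l7, p4)
        g = self.c3k2(bb.l8, g)
        g = self.sppf(bb.l9, g)
        p5 = self.c2psa(bb.l10, g)
        return p2, p3, p4, p5

    def model(self, net):
        gin = self.new(3, "input")
        gin.protected = True
        if isinstance(net, YOLO11nBaseline):
            _, p3, p4, p5 = self.backbone(net.backbone, gin)
            t13 = self.c3k2(net.n13, [(p5, p5.find().width), (p4, p4.find().width)])
            t16 = self.c3k2(net.n16, [(t13, t13.find().width), (p3, p3.find().width)])
            d = self.convbn(net.d17, t16)
            t19 = self.c3k2(net.n19, [(d, d.width), (t13, t13.find().width)])
            d = self.convbn(net.d20, t19)
            t22 = self.c3k2(net.n22, [(d, d.width), (p5, p5.find().width)])
            self.detect(net.detect, [t16, t19, t22])
        elif isinstance(net, StemNodeNet):
            p2, p3, p4, p5 = self.backbone(net.backbone, gin)
            nk: ASFP2Neck = net.neck
            t4 = self.c3k2(nk.n4, self.tfe(nk.tfe4, p3, p4, p5))
            t3 = self.c3k2(nk.n3, self.tfe(nk.tfe3, p2, p3, t4))
            t2 = self.c3k2(nk.n2, [(t3, t3.find().width), (p2, p2.find().width)])
            d2 = self.convbn(nk.d2, t2)
            u3 = self.c3k2(nk.n3b, [(d2, d2.width), (t3, t3.find().width)])
            sf = self.ssff(nk.ssff, [p2, p3, p4, p5])
            u3 = self.attnadd(nk.add3, u3, sf)
            d3 = self.convbn(nk.d3, u3)
            u4 = self.c3k2(nk.n4b, [(d3, d3.width), (t4, t4.find().width)])
            d4 = self.convbn(nk.d4, u4)
            u5 = self.c3k2(nk.n5b, [(d4, d4.width), (p5, p5.find().width)])
            feats = [t2, u3, u4, u5]
            if isinstance(net.head, LSDECDHead):
                self.lsdecd(net.head, feats)
            else:
                self.detect(net.head, feats)
        else:
            raise TypeError(f"cannot trace channels of {type(net).__name__}")
        return self


def trace_groups(net) -> list[Group]:
    """Coupled channel groups of a built model (deduplicated roots)."""
    tr = _Tracer().model(net)
    roots, seen = [], set()
    for g in tr.groups:
        r = g.find()
        if id(r) not in seen:
            seen.add(id(r))
            roots.append(r)
    return roots


# ---------------------------------------------------------------------------
# importance and pruning
# ---------------------------------------------------------------------------

def _group_l1(g: Group) -> np.ndarray:
    """Aggregated per-channel l1 magnitude over the group's producers."""
    v = np.zeros(g.width, dtype=np.float64)
    for conv, off in g.producers:
        w = conv.weight.data
        v += np.abs(w).reshape(w.shape[0], -1).sum(axis=1)[off:off + g.width]
    for conv in g.dw:
        w = conv.weight.data
        v += np.abs(w).reshape(w.shape[0], -1).sum(axis=1)
    if not g.producers and not g.dw:
        v[:] = np.inf  # input group: never comparable
    return v


def _scores_for(groups) -> dict:
    """LAMP scores per group, over its currently live channels."""
    out = {}
    for g in groups:
        v = _group_l1(g)
        s = np.full(g.width, np.inf)
        live = np.flatnonzero(g.keep)
        if live.size and np.all(np.isfinite(v[live])):
            vl = v[live]
            order = np.argsort(vl, kind="stable")
            s_sorted = lamp_score(LayerWeightView(g.name, vl[order], order))
            sl = np.empty_like(s_sorted)
            sl[order] = s_sorted
            s[live] = sl
        out[g] = s
    return out


def channel_importance(net) -> dict:
    """Per-group LAMP scores of the aggregated channel magnitudes.

    Returns ``{group: scores}`` with scores aligned to channel position;
    scores are comparable across groups (that is LAMP's point).
    """
    return _scores_for(trace_groups(net))


@dataclass(frozen=True)
class PruneSchedule:
    steps: int = 200
    speed_up: float = 3.0
    max_sparsity: float = 1.0
    reg: float = 0.0005
    min_channels: int = 2
    input_size: int = 640

    def __post_init__(self):
        if self.speed_up <= 0 or not (0 < self.max_sparsity <= 1.0):
            raise ValueError("invalid schedule")


@dataclass
class PruneReport:
    layers: list = field(default_factory=list)   # per-group channel counts
    params_before: int = 0
    params_after: int = 0
    gflops_before: float = 0.0
    gflops_after: float = 0.0
    achieved_speed_up: float = 0.0
    target_reached: bool = True

    def as_dict(self):
        return {"layers": list(self.layers),
                "params_before": self.params_before,
                "params_after": self.params_after,
                "gflops_before": self.gflops_before,
                "gflops_after": self.gflops_after,
                "achieved_speed_up": self.achieved_speed_up,
                "target_reached": self.target_reached}


def _conv_segments(groups):
    """Reverse maps conv -> [(group, off, width)] for in and out sides."""
    ins, outs, dws = {}, {}, {}
    for g in groups:
        for conv, off in g.producers:
            outs.setdefault(conv, []).append((g, off))
        for conv, off in g.consumers:
            ins.setdefault(conv, []).append((g, off))
        for conv in g.dw:
            dws[conv] = g
    return ins, outs, dws


def _flops_estimate(ins, outs, dws) -> float:
    """MACs with current live widths, using recorded per-conv output areas."""
    total = 0.0
    convs = set(ins) | set(outs) | set(dws)
    for conv in convs:
        hw = getattr(conv, "last_out_hw", None)
        if hw is None:
            continue
        if conv in dws:
            total += dws[conv].live * conv.k * conv.k * hw
            continue
        cin = sum(g.live for g, _ in ins.get(conv, [])) if conv in ins else conv.cin
        cout = sum(g.live for g, _ in outs.get(conv, [])) if conv in outs else conv.cout
        total += cin * cout * conv.k * conv.k * hw
    return total


def _deconv_flops(net) -> float:
    total = 0.0
    for m in net.modules():
        if isinstance(m, DEConv):
            hw = getattr(m, "last_out_hw", None)
            if hw:
                total += m.dim * m.dim * 9 * hw
    return total


def prune(net, sched: PruneSchedule | None = None):
    """Iterative LAMP channel pruning toward a FLOP speed-up target.

    Returns ``(net, PruneReport)``; the network is modified in place
    (weights physically sliced) and keeps its input/output signature —
    only interior widths change.
    """
    sched = sched or PruneSchedule()
    report = PruneReport()
    report.params_before = net.param_count(fused=True)
    macs0 = profile_macs(net, (1, 3, sched.input_size, sched.input_size))
    report.gflops_before = round(2 * macs0 / 1e9, 2)

    groups = trace_groups(net)
    ins, outs, dws = _conv_segments(groups)
    fixed = _deconv_flops(net)
    before_widths = {g: g.width for g in groups}

    def floor_of(g):
        return max(sched.min_channels,
                   int(np.ceil(g.width * (1.0 - sched.max_sparsity))))

    f_start = _flops_estimate(ins, outs, dws) + fixed
    f_cur = f_start
    reached = False
    for t in range(1, sched.steps + 1):
        ratio_t = 1.0 + (sched.speed_up - 1.0) * t / sched.steps
        budget = f_start / ratio_t
        imp = _scores_for(groups)
        # candidate channels: (score, group, channel)
        cand = []
        for g in groups:
            if g.protected:
                continue
            s = imp[g]
            for j in np.flatnonzero(g.keep):
                cand.append((s[j], g, j))
        cand.sort(key=lambda x: x[0])
        k = 0
        while f_cur > budget and k < len(cand):
            _, g, j = cand[k]
            k += 1
            if g.live <= floor_of(g):
                continue
            g.keep[j] = False
            f_cur = _flops_estimate(ins, outs, dws) + fixed
        # linearly incremented magnitude regularization on the channels
        # closest to the current frontier
        shrink = max(0.0, 1.0 - sched.reg * t)
        for _, g, j in cand[k:k + 16]:
            if not g.keep[j]:
                continue
            for conv, off in g.producers:
                conv.weight.data[off + j] *= shrink
        if f_cur <= f_start / sched.speed_up:
            reached = True
            break

    if not reached:
        prunable = any(not g.protected and g.live > floor_of(g) for g in groups)
        if prunable:
            warnings.warn("pruning stopped before reaching the speed-up target",
                          stacklevel=2)
    _apply_slicing(net, groups, ins, outs, dws)

    macs1 = profile_macs(net, (1, 3, sched.input_size, sched.input_size))
    report.params_after = net.param_count(fused=True)
    report.gflops_after = round(2 * macs1 / 1e9, 2)
    report.achieved_speed_up = macs0 / max(macs1, 1)
    report.target_reached = report.achieved_speed_up >= sched.speed_up - 1e-6
    report.layers = [{"layer": g.name, "before": before_widths[g],
                      "after": g.live} for g in groups]
    return net, report


def _apply_slicing(net, groups, ins, outs, dws):
    """Physically remove dropped channels from every affected tensor."""
    out_mask: dict = {}
    in_mask: dict = {}
    for g in groups:
        for conv, off in g.producers:
            m = out_mask.setdefault(conv, np.ones(conv.cout, dtype=bool))
            m[off:off + g.width] = g.keep
        for conv, off in g.consumers:
            m = in_mask.setdefault(conv, np.ones(conv.cin, dtype=bool))
            m[off:off + g.width] = g.keep
        for mod, idx in g.split_refs:
            mod.split[idx] = g.live
        for norm, off in g.norms:
            nm = out_mask.setdefault(norm, np.ones(norm.c if hasattr(norm, "c")
                                                   else norm.weight.size, dtype=bool))
            nm[off:off + g.width] = g.keep
    for conv, g in dws.items():
        out_mask.setdefault(conv, np.ones(conv.cout, dtype=bool))[:] = g.keep
        in_mask.setdefault(conv, np.ones(conv.cin, dtype=bool))[:] = g.keep

    for mod, mask in out_mask.items():
        if isinstance(mod, Conv2d):
            mod.weight.data = mod.weight.data[mask]
            if mod.bias is not None:
                mod.bias.data = mod.bias.data[mask]
            mod.cout = int(mask.sum())
            if mod.groups > 1:
                mod.groups = mod.cout
        elif isinstance(mod, BatchNorm2d):
            mod.weight.data = mod.weight.data[mask]
            mod.bias.data = mod.bias.data[mask]
            mod.running_mean = mod.running_mean[mask]
            mod.running_var = mod.running_var[mask]
            mod.c = int(mask.sum())
        elif isinstance(mod, GroupNorm):  # only whole-group masks reach here
            mod.weight.data = mod.weight.data[mask]
            mod.bias.data = mod.bias.data[mask]
            mod.c = int(mask.sum())
    for conv, mask in in_mask.items():
        if conv.groups == 1:
            conv.weight.data = conv.weight.data[:, mask]
            conv.cin = int(mask.sum())
        else:
            conv.cin = int(mask.sum())
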
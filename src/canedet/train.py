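"""Micro-scale training, prediction and fine-tuning orchestration.

The loop wires the pieces the way the full-scale recipe does: the
improved network, distribution-focal + Shape-IoU box regression, BCE
classification, SGD (lr 0.01, momentum 0.9), and soft suppression at
inference.  Assignment is a static center-inside-box rule with a
scale-matched pyramid level per target — a deliberately simple stand-in
for dynamic task-aligned matching that behaves well at the tiny problem
sizes this package trains at.

Paper-scale defaults (640 px, 200 epochs, batch 16) are kept in
``RunConfig``; ``RunConfig.micro()`` is the preset the test-suite runs:
small synthetic scenes, a few epochs, minutes on one CPU.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .assembly import ModelSpec, build_model
from .blocks import dfl_expectation
from .boxgeom import Box, BoxFormat, ShapeIoUParams, shape_iou_loss
from .metrics import MatchConfig, evaluate
from .nn.autograd import Tensor, no_grad
from .nn.optim import SGD
from .suppress import Detection, SuppressConfig, suppress
from .synth import SceneConfig, generate_scene

__all__ = ["RunConfig", "train", "predict", "finetune",
           "save_checkpoint", "load_checkpoint", "build_memory_dataset"]


@dataclass(frozen=True)
class RunConfig:
    input_size: int = 640
    lr0: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    optimizer: str = "sgd"
    batch: int = 16
    epochs: int = 200
    seed: int = 0
    variant: str = "ours"
    loss: ShapeIoUParams = field(default_factory=ShapeIoUParams)
    suppress: SuppressConfig = field(default_factory=SuppressConfig)
    box_weight: float = 5.0
    cls_weight: float = 1.0
    dfl_weight: float = 0.5
    conf_threshold: float = 0.1
    max_candidates: int = 300   # score top-k cap ahead of suppression

    @staticmethod
    def micro(seed: int = 0, variant: str = "ours", epochs: int = 12) -> "RunConfig":
        """CPU-scale preset used by the test-suite and worked examples."""
        return RunConfig(input_size=128, batch=4, epochs=epochs, seed=seed,
                         variant=variant, lr0=0.01)


def micro_scene_config(seed: int = 0, image_size: int = 128) -> SceneConfig:
    """Scene layout for micro training: sparse, high-contrast, unoccluded."""
    return SceneConfig(image_size=image_size, n_stalks=(1, 2),
                       nodes_per_stalk=(1, 3),
                       stalk_width_frac=(0.12, 0.3),
                       node_aspect=(1.5, 3.0),
                       occlusion_prob=0.0, illumination=0.15, seed=seed)


def build_memory_dataset(n_images: int, scene: SceneConfig, seed: int = 0,
                         split_ratio: float = 0.8):
    """In-memory train/val dataset of synthetic scenes."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_images)
    n_train = int(round(split_ratio * n_images))
    train, val = [], []
    for i in range(n_images):
        cfg = replace(scene, seed=seed * 100003 + i)
        img, boxes = generate_scene(cfg)
        (train if int(np.flatnonzero(order == i)[0]) < n_train else val
         ).append((img, boxes))
    return train, val


# ---------------------------------------------------------------------------
# assignment and loss
# ---------------------------------------------------------------------------

def _level_of(box: Box, strides) -> int:
    """Scale-matched pyramid level: stride closest to size/4."""
    size = float(max(box.w, box.h))
    tgt = size / 4.0
    return int(np.argmin([abs(np.log((s + 1e-9) / (tgt + 1e-9))) for s in strides]))


def assign_targets(boxes: list[Box], strides, sizes, reg_max: int = 16):
    """Static center-inside assignment.

    Returns a list over levels of dicts with anchor indices, class
    targets and ltrb distance targets (in stride units, clipped into the
    DFL range).
    """
    out = []
    offsets = []
    for (h, w) in sizes:
        out.append({"pos": [], "ltrb": [], "boxes": []})
        offsets.append((h, w))
    for b in boxes:
        li = _level_of(b, strides)
        s = strides[li]
        h, w = sizes[li]
        x1, y1 = b.xc - b.w / 2, b.yc - b.h / 2
        x2, y2 = b.xc + b.w / 2, b.yc + b.h / 2
        cx0 = int(np.clip(np.floor(x1 / s - 0.5) + 1, 0, w - 1))
        cx1 = int(np.clip(np.ceil(x2 / s - 0.5) - 1, 0, w - 1))
        cy0 = int(np.clip(np.floor(y1 / s - 0.5) + 1, 0, h - 1))
        cy1 = int(np.clip(np.ceil(y2 / s - 0.5) - 1, 0, h - 1))
        # always include the cell containing the center
        ccx = int(np.clip(b.xc / s - 0.5, 0, w - 1))
        ccy = int(np.clip(b.yc / s - 0.5, 0, h - 1))
        cells = {(ccy, ccx)}
        for gy in range(cy0, cy1 + 1):
            for gx in range(cx0, cx1 + 1):
                cells.add((gy, gx))
        # cap the footprint at the 9 cells nearest the center
        cells = sorted(cells, key=lambda c: (c[0] + 0.5 - b.yc / s) ** 2 +
                       (c[1] + 0.5 - b.xc / s) ** 2)[:9]
        for (gy, gx) in cells:
            ax, ay = (gx + 0.5) * s, (gy + 0.5) * s
            ltrb = np.array([ax - x1, ay - y1, x2 - ax, y2 - ay]) / s
            if ltrb.min() <= 0:
                continue
            out[li]["pos"].append(gy * sizes[li][1] + gx)
            out[li]["ltrb"].append(np.clip(ltrb, 0.01, reg_max - 1.01))
            out[li]["boxes"].append(b)
    return out


def _bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    soft = (1.0 + (0.0 - z.abs()).exp()).log()
    return z.maximum(0.0) - z * y + soft


def detection_loss(level_maps, targets_per_image, strides, cfg: RunConfig,
                   reg_max: int = 16):
    """Composite loss over a batch: BCE cls + DFL + Shape-IoU box."""
    n = level_maps[0].shape[0]
    cls_terms = []
    box_terms = []
    dfl_terms = []
    n_pos = 0
    for li, m in enumerate(level_maps):
        _, c, h, w = m.shape
        flat = m.reshape(n, c, h * w)
        cls_logits = flat[:, 4 * reg_max:]
        # classification target map
        y = np.zeros((n, cls_logits.shape[1], h * w), dtype=np.float32)
        pos_rows, ltrbs = [], []
        for bi in range(n):
            t = targets_per_image[bi][li]
            for k, a in enumerate(t["pos"]):
                y[bi, 0, a] = 1.0
                pos_rows.append((bi, a, t["ltrb"][k], t["boxes"][k]))
        cls_terms.append(_bce_with_logits(cls_logits, y).sum())
        if not pos_rows:
            continue
        n_pos += len(pos_rows)
        bidx = np.array([r[0] for r in pos_rows])
        aidx = np.array([r[1] for r in pos_rows])
        ltrb_t = np.stack([r[2] for r in pos_rows]).astype(np.float32)
        dist = flat[:, : 4 * reg_max]
        sel = dist.transpose((0, 2, 1))[bidx, aidx]      # (P, 4*reg_max)
        P = sel.shape[0]
        z = sel.reshape(P, 4, reg_max)
        # distribution-focal: CE against the two bins flanking the target
        zmax = Tensor(z.data.max(axis=2, keepdims=True))
        logsum = ((z - zmax).exp().sum(axis=2, keepdims=True)).log() + zmax
        logp = z - logsum
        li_bin = np.floor(ltrb_t).astype(int)
        ri_bin = li_bin + 1
        wl = (ri_bin - ltrb_t).astype(np.float32)
        wr = (ltrb_t - li_bin).astype(np.float32)
        rows = np.repeat(np.arange(P), 4)
        cols = np.tile(np.arange(4), P)
        nll = -(logp[rows, cols, li_bin.ravel()] * wl.ravel()
                + logp[rows, cols, ri_bin.ravel()] * wr.ravel())
        dfl_terms.append(nll.sum())
        # expected distances -> predicted box, Shape-IoU against gt
        probs = logp.exp()
        exp_d = (probs * np.arange(reg_max, dtype=np.float32)).sum(axis=2)
        s = strides[li]
        hsz = level_maps[li].shape[3]
        ax = ((aidx % w) + 0.5) * s
        ay = ((aidx // w) + 0.5) * s
        x1 = Tensor(ax) - exp_d[:, 0] * s
        y1 = Tensor(ay) - exp_d[:, 1] * s
        x2 = Tensor(ax) + exp_d[:, 2] * s
        y2 = Tensor(ay) + exp_d[:, 3] * s
        from .nn.autograd import stack as tstack
        pred = tstack([(x1 + x2) * 0.5, (y1 + y2) * 0.5,
                       (x2 - x1).maximum(1e-3), (y2 - y1).maximum(1e-3)], axis=1)
        gt = np.stack([[b.xc, b.yc, b.w, b.h] for _, _, _, b in pos_rows]
                      ).astype(np.float32)
        res = shape_iou_loss(pred, Tensor(gt), cfg.loss)
        box_terms.append(res.loss.sum())

    total_anchors = sum(m.shape[2] * m.shape[3] for m in level_maps) * n
    denom = max(n_pos, 1)
    cls_l = sum(cls_terms[1:], cls_terms[0]) * (1.0 / total_anchors)
    loss = cls_l * cfg.cls_weight
    parts = {"cls": float(cls_l.item())}
    if box_terms:
        box_l = sum(box_terms[1:], box_terms[0]) * (1.0 / denom)
        dfl_l = sum(dfl_terms[1:], dfl_terms[0]) * (1.0 / (4 * denom))
        loss = loss + box_l * cfg.box_weight + dfl_l * cfg.dfl_weight
        parts["box"] = float(box_l.item())
        parts["dfl"] = float(dfl_l.item())
    parts["n_pos"] = n_pos
    return loss, parts


# ---------------------------------------------------------------------------
# train / predict / finetune
# ---------------------------------------------------------------------------

def _to_input(images) -> Tensor:
    arr = np.stack([im.astype(np.float32) / 255.0 for im in images])
    return Tensor(arr.transpose(0, 3, 1, 2))


def _epoch(net, data, cfg, opt, rng, reg_max=16):
    order = rng.permutation(len(data))
    logs = []
    for start in range(0, len(order), cfg.batch):
        idx = order[start:start + cfg.batch]
        images = [data[i][0] for i in idx]
        targets = []
        sizes = None
        x = _to_input(images)
        maps = net(x)
        sizes = [(m.shape[2], m.shape[3]) for m in maps]
        for i in idx:
            targets.append(assign_targets(data[i][1], net.strides, sizes, reg_max))
        loss, parts = detection_loss(maps, targets, net.strides, cfg, reg_max)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(
                f"training diverged: non-finite loss {parts}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        parts["loss"] = float(loss.item())
        logs.append(parts)
    return logs


def train(net, data_train, data_val, cfg: RunConfig, log_path=None):
    """Train in place; returns per-epoch history (losses and val mAP50)."""
    if not data_train:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(net.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    history = []
    for ep in range(cfg.epochs):
        net.train()
        t0 = time.time()
        logs = _epoch(net, data_train, cfg, opt, rng)
        mean_loss = float(np.mean([l["loss"] for l in logs]))
        rec = {"epoch": ep, "loss": mean_loss,
               "time_s": round(time.time() - t0, 2)}
        if data_val:
            res = evaluate_model(net, data_val, cfg)
            rec["val_map50"] = res.map50
        history.append(rec)
        if log_path:
            with open(log_path, "a") as f:
                f.write(json.dumps(rec) + "\n")
    return history


def predict(net, images, cfg: RunConfig | None = None) -> list[list[Detection]]:
    """Forward + decode + soft suppression; one Detection list per image."""
    cfg = cfg or RunConfig()
    net.eval()
    out = []
    reg_max = 16
    for img in images:
        with no_grad():
            maps = net(_to_input([img]))
        dets = []
        for li, m in enumerate(maps):
            s = net.strides[li]
            _, c, h, w = m.shape
            arr = m.data[0].reshape(c, h * w).T        # (A, C)
            cls = 1.0 / (1.0 + np.exp(-arr[:, 4 * reg_max:]))
            conf = cls.max(axis=1)
            keep = np.flatnonzero(conf >= cfg.conf_threshold)
            if keep.size == 0:
                continue
            d = dfl_expectation(arr[keep, : 4 * reg_max], reg_max)
            ax = ((keep % w) + 0.5) * s
            ay = ((keep // w) + 0.5) * s
            x1, y1 = ax - d[:, 0] * s, ay - d[:, 1] * s
            x2, y2 = ax + d[:, 2] * s, ay + d[:, 3] * s
            for i in range(keep.size):
                wdt, hgt = max(x2[i] - x1[i], 1e-3), max(y2[i] - y1[i], 1e-3)
                dets.append(Detection(
                    Box(float((x1[i] + x2[i]) / 2), float((y1[i] + y2[i]) / 2),
                        float(wdt), float(hgt), format=BoxFormat.CENTER_PIXEL),
                    score=float(np.clip(conf[keep[i]], 0.0, 1.0)),
                    cls=int(cls[keep[i]].argmax())))
        if len(dets) > cfg.max_candidates:
            dets = sorted(dets, key=lambda d: -d.score)[: cfg.max_candidates]
        out.append(suppress(dets, cfg.suppress))
    return out


def evaluate_model(net, data, cfg: RunConfig | None = None,
                   match: MatchConfig | None = None):
    cfg = cfg or RunConfig()
    preds = predict(net, [im for im, _ in data], cfg)
    gts = [b for _, b in data]
    return evaluate(preds, gts, match or MatchConfig())


def finetune(net, data_train, data_val, cfg: RunConfig, epochs: int | None = None):
    """Post-pruning retraining at a reduced learning rate."""
    if epochs == 0:
        return net, []
    ft = replace(cfg, epochs=epochs or cfg.epochs, lr0=cfg.lr0 * 0.5)
    hist = train(net, data_train, data_val, ft)
    return net, hist


def save_checkpoint(net, path, spec: ModelSpec | None = None):
    sd = net.state_dict()
    meta = {"variant": getattr(net, "variant", "yolo11n")}
    if spec is not None:
        meta["spec_yaml"] = spec.to_yaml()
    np.savez_compressed(path, __meta__=json.dumps(meta),
                        **{k.replace("/", "_"): v for k, v in sd.items()})


def load_checkpoint(path, net=None):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    if net is None:
        net = build_model(meta.get("variant", "ours"))
    sd = {k: data[k] for k in data.files if k != "__meta__"}
    net.load_state_dict(sd)
    return net
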
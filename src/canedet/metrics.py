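"""Detection evaluation: precision, recall, AP/mAP, and size-binned mAP.

Follows the de-facto COCO conventions: greedy per-image matching by
descending confidence (each ground truth claimed at most once, best
remaining IoU wins), 101-point interpolated average precision, mAP50 at
IoU 0.5 and mAP50:95 averaged over IoU 0.50–0.95 in steps of 0.05.  The
size-binned harness restricts scoring to small / medium / large boxes by
area with ignore semantics for out-of-bin matches, so a detector can be
probed specifically on the tiny stem nodes the stride-4 path exists for.

Precision and recall are reported at the maximum-F1 point of the
confidence sweep (IoU 0.5) unless a fixed ``conf_threshold`` is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxgeom import Box, iou
from .suppress import Detection
from .synth import SIZE_BIN_CUTOFFS, size_bin

__all__ = ["MatchConfig", "EvalResult", "match_detections",
           "precision_recall", "evaluate", "DEFAULT_IOU_THRESHOLDS"]

DEFAULT_IOU_THRESHOLDS = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass(frozen=True)
class MatchConfig:
    iou_thresholds: tuple = DEFAULT_IOU_THRESHOLDS
    conf_threshold: float | None = None     # None -> report P/R at max F1
    size_bins: tuple = SIZE_BIN_CUTOFFS

    def __post_init__(self):
        t = np.asarray(self.iou_thresholds)
        if not (np.all(np.diff(t) > 0) and np.all((t > 0) & (t < 1))):
            raise ValueError("iou_thresholds must be ascending within (0,1)")


@dataclass
class EvalResult:
    precision: float
    recall: float
    map50: float
    map50_95: float
    per_bin_map50: dict = field(default_factory=dict)
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "map50": self.map50, "map50_95": self.map50_95,
                "per_bin_map50": dict(self.per_bin_map50),
                "tp": self.tp, "fp": self.fp, "fn": self.fn}


def _iou_matrix(preds: list[Detection], gts: list[Box]) -> np.ndarray:
    m = np.zeros((len(preds), len(gts)))
    for i, d in enumerate(preds):
        for j, g in enumerate(gts):
            m[i, j] = iou(d.box, g)
    return m


def _greedy_match(preds, gts, thr, iou_mat=None):
    """Greedy one-to-one assignment at one IoU threshold.

    ``preds`` must already be sorted by descending score.  Returns an array
    of matched gt indices (-1 for unmatched predictions).
    """
    m = _iou_matrix(preds, gts) if iou_mat is None else iou_mat
    taken = np.zeros(len(gts), dtype=bool)
    match = np.full(len(preds), -1, dtype=int)
    for i in range(len(preds)):
        best_j, best_v = -1, thr
        for j in range(len(gts)):
            if not taken[j] and m[i, j] >= best_v:
                best_j, best_v = j, m[i, j]
        if best_j >= 0:
            taken[best_j] = True
            match[i] = best_j
    return match


def match_detections(preds: list[Detection], gts: list[Box],
                     cfg: MatchConfig | None = None) -> dict:
    """Per-image TP/FP/FN counts for every IoU threshold in the config."""
    cfg = cfg or MatchConfig()
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    sp = [preds[i] for i in order]
    m = _iou_matrix(sp, gts)
    out = {}
    for t in cfg.iou_thresholds:
        match = _greedy_match(sp, gts, t, m)
        tp = int((match >= 0).sum())
        out[float(t)] = {"tp": tp, "fp": len(preds) - tp, "fn": len(gts) - tp}
    return out


def precision_recall(counts: dict) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); 0/0 is defined as 0 with a warning."""
    tp, fp, fn = counts["tp"], counts["fp"], counts["fn"]
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0 or tp + fn == 0:
        warnings.warn("precision/recall undefined (0/0); reporting 0",
                      stacklevel=2)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


def _ap_101(scores, flags, n_gt) -> float:
    """101-point interpolated AP from per-detection TP flags."""
    if n_gt == 0:
        return 0.0
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores), kind="stable")
    tp = np.asarray(flags, dtype=float)[order]
    fp = 1.0 - tp
    ctp, cfp = np.cumsum(tp), np.cumsum(fp)
    recall = ctp / n_gt
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    # precision envelope, then sample at 101 recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        idx = np.searchsorted(recall, r, side="left")
        ap += env[idx] if idx < len(env) else 0.0
    return ap / 101.0


def _collect(preds_by_image, gts_by_image, thr, bin_name=None, cutoffs=SIZE_BIN_CUTOFFS):
    """Dataset-wide (score, tp) pairs at one threshold, with size-bin
    ignore semantics when ``bin_name`` is given."""
    scores, flags = [], []
    n_gt = 0
    for preds, gts in zip(preds_by_image, gts_by_image):
        order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
        sp = [preds[i] for i in order]
        if bin_name is None:
            match = _greedy_match(sp, gts, thr)
            n_gt += len(gts)
            for i, d in enumerate(sp):
                scores.append(d.score)
                flags.append(1.0 if match[i] >= 0 else 0.0)
        else:
            in_bin = [_bin_of(g, cutoffs) == bin_name for g in gts]
            match = _greedy_match(sp, gts, thr)
            n_gt += sum(in_bin)
            for i, d in enumerate(sp):
                j = match[i]
                if j >= 0:
                    if in_bin[j]:
                        scores.append(d.score)
                        flags.append(1.0)
                    # matched an out-of-bin gt: ignored
                elif _bin_of_box(d.box, cutoffs) == bin_name:
                    scores.append(d.score)
                    flags.append(0.0)
                # unmatched and outside the bin: ignored
    return scores, flags, n_gt


def _bin_of_box(b: Box, cutoffs) -> str:
    a = float(b.w * b.h)
    if a < cutoffs[0]:
        return "small"
    if a < cutoffs[1]:
        return "medium"
    return "large"


def _bin_of(g: Box, cutoffs) -> str:
    return _bin_of_box(g, cutoffs)


def evaluate(preds_by_image, gts_by_image, cfg: MatchConfig | None = None) -> EvalResult:
    """Dataset-level evaluation.

    ``preds_by_image`` is a list (one entry per image) of Detection lists;
    ``gts_by_image`` the matching list of ground-truth Box lists.
    """
    cfg = cfg or MatchConfig()
    if len(preds_by_image) != len(gts_by_image):
        raise ValueError("prediction and ground-truth image lists differ in length")

    aps = []
    for t in cfg.iou_thresholds:
        s, f, n = _collect(preds_by_image, gts_by_image, t)
        aps.append(_ap_101(s, f, n))
    thr = np.asarray(cfg.iou_thresholds)
    if np.any(np.abs(thr - 0.5) < 1e-9):
        map50 = aps[int(np.argmin(np.abs(thr - 0.5)))]
    else:
        s, f, n = _collect(preds_by_image, gts_by_image, 0.5)
        map50 = _ap_101(s, f, n)
    map50_95 = float(np.mean(aps))

    per_bin = {}
    for name in ("small", "medium", "large"):
        s, f, n = _collect(preds_by_image, gts_by_image, 0.5, name, cfg.size_bins)
        per_bin[name] = _ap_101(s, f, n)

    # P/R at IoU 0.5: fixed confidence, or the max-F1 point of the sweep
    s, f, n_gt = _collect(preds_by_image, gts_by_image, 0.5)
    s = np.asarray(s)
    f = np.asarray(f)
    if len(s) == 0:
        if n_gt:
            warnings.warn("no detections: recall 0", stacklevel=2)
        return EvalResult(0.0, 0.0, map50, map50_95, per_bin, 0, 0, n_gt)
    order = np.argsort(-s, kind="stable")
    s, f = s[order], f[order]
    ctp = np.cumsum(f)
    cfp = np.cumsum(1.0 - f)
    if cfg.conf_threshold is not None:
        k = int(np.sum(s >= cfg.conf_threshold))
        k = max(k, 0)
        tp = int(ctp[k - 1]) if k else 0
        fp = int(cfp[k - 1]) if k else 0
    else:
        prec = ctp / np.maximum(ctp + cfp, 1e-12)
        rec = ctp / max(n_gt, 1)
        f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
        k = int(np.argmax(f1)) + 1
        tp, fp = int(ctp[k - 1]), int(cfp[k - 1])
    fn = n_gt - tp
    p, r = precision_recall({"tp": tp, "fp": fp, "fn": fn}) if (tp or fp or fn) \
        else (0.0, 0.0)
    return EvalResult(p, r, map50, map50_95, per_bin, tp, fp, fn)
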
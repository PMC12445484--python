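"""Independent reference implementations used as test oracles.

Everything here is deliberately written against the *definitions* —
pixel counting for areas, literal score-update formulas for
suppression, a COCOeval-style table evaluator for AP — and stays
independent of the package's implementation paths.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# rasterized box geometry
# ---------------------------------------------------------------------------

def raster_iou(b1, b2, grid: int = 400) -> float:
    """IoU by counting cells of a fine grid covering both boxes."""
    def corners(b):
        return b[0] - b[2] / 2, b[1] - b[3] / 2, b[0] + b[2] / 2, b[1] + b[3] / 2

    x1a, y1a, x2a, y2a = corners(b1)
    x1b, y1b, x2b, y2b = corners(b2)
    lo_x, hi_x = min(x1a, x1b), max(x2a, x2b)
    lo_y, hi_y = min(y1a, y1b), max(y2a, y2b)
    xs = np.linspace(lo_x, hi_x, grid, endpoint=False) + (hi_x - lo_x) / grid / 2
    ys = np.linspace(lo_y, hi_y, grid, endpoint=False) + (hi_y - lo_y) / grid / 2
    X, Y = np.meshgrid(xs, ys)
    in_a = (X >= x1a) & (X <= x2a) & (Y >= y1a) & (Y <= y2a)
    in_b = (X >= x1b) & (X <= x2b) & (Y >= y1b) & (Y <= y2b)
    inter = np.count_nonzero(in_a & in_b)
    union = np.count_nonzero(in_a | in_b)
    return inter / union if union else 0.0


def exact_iou(b1, b2) -> float:
    """Closed-form IoU for (xc, yc, w, h) boxes."""
    ax1, ay1 = b1[0] - b1[2] / 2, b1[1] - b1[3] / 2
    ax2, ay2 = b1[0] + b1[2] / 2, b1[1] + b1[3] / 2
    bx1, by1 = b2[0] - b2[2] / 2, b2[1] - b2[3] / 2
    bx2, by2 = b2[0] + b2[2] / 2, b2[1] + b2[3] / 2
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = b1[2] * b1[3] + b2[2] * b2[3] - inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# straight-from-formula suppression
# ---------------------------------------------------------------------------

def _shape_sim(b1, b2, alpha) -> float:
    pen = math.exp(-alpha * abs(b1[2] / b1[3] - b2[2] / b2[3]))
    return exact_iou(b1, b2) * pen


def formula_suppress(boxes, scores, mode, nt=0.5, sigma=0.5,
                     score_floor=1e-3, alpha=1.5):
    """Literal greedy suppression over (box, score) lists.

    Ties: higher score, then larger area, then lower original index.
    Returns kept (index, score) pairs in keep order.
    """
    pool = [(i, list(b), s) for i, (b, s) in enumerate(zip(boxes, scores))]
    kept = []
    while pool:
        best = max(range(len(pool)),
                   key=lambda k: (pool[k][2], pool[k][1][2] * pool[k][1][3],
                                  -pool[k][0]))
        i, mb, ms = pool.pop(best)
        kept.append((i, ms))
        nxt = []
        for j, b, s in pool:
            if mode == "hard":
                if exact_iou(mb, b) > nt:
                    continue
                nxt.append((j, b, s))
            elif mode == "linear":
                v = exact_iou(mb, b)
                s2 = s * (1.0 - v) if v > nt else s
                if s2 > score_floor:
                    nxt.append((j, b, s2))
            else:  # gaussian with shape-aware similarity, ungated
                v = _shape_sim(mb, b, alpha)
                s2 = s * math.exp(-(v * v) / sigma)
                if s2 > score_floor:
                    nxt.append((j, b, s2))
        pool = nxt
    return kept


# ---------------------------------------------------------------------------
# COCOeval-style AP (independent evaluator)
# ---------------------------------------------------------------------------

def cocoeval_ap(preds_by_image, gts_by_image, thr=0.5, n_points=101):
    """Average precision following the COCOeval table algorithm.

    ``preds_by_image``: list of (boxes, scores) with (xc, yc, w, h) rows;
    ``gts_by_image``: list of box arrays.  Differs structurally from the
    package evaluator: per-image match tables are built first, then
    merged and integrated with the recall-indexed precision table.
    """
    matched_flags = []
    all_scores = []
    n_gt = 0
    for (boxes, scores), gts in zip(preds_by_image, gts_by_image):
        n_gt += len(gts)
        order = sorted(range(len(scores)), key=lambda i: -scores[i])
        gt_taken = [False] * len(gts)
        for i in order:
            best, best_iou = -1, thr
            for j in range(len(gts)):
                if gt_taken[j]:
                    continue
                v = exact_iou(boxes[i], gts[j])
                if v >= best_iou:
                    best, best_iou = j, v
            if best >= 0:
                gt_taken[best] = True
                matched_flags.append(1)
            else:
                matched_flags.append(0)
            all_scores.append(scores[i])
    if n_gt == 0 or not all_scores:
        return 0.0
    order = np.argsort(-np.asarray(all_scores), kind="stable")
    tp = np.asarray(matched_flags, dtype=float)[order]
    ctp = np.cumsum(tp)
    cfp = np.cumsum(1 - tp)
    rc = ctp / n_gt
    pr = ctp / np.maximum(ctp + cfp, 1e-12)
    # COCOeval: precision envelope from the right, sampled on recThrs
    for i in range(len(pr) - 1, 0, -1):
        pr[i - 1] = max(pr[i - 1], pr[i])
    rec_thrs = np.linspace(0, 1, n_points)
    idx = np.searchsorted(rc, rec_thrs, side="left")
    q = np.zeros(n_points)
    for k, i in enumerate(idx):
        if i < len(pr):
            q[k] = pr[i]
    return float(q.mean())


# ---------------------------------------------------------------------------
# numerical gradients
# ---------------------------------------------------------------------------

def numerical_grad(fn, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        f1 = fn(x)
        x[i] = orig - eps
        f0 = fn(x)
        x[i] = orig
        g[i] = (f1 - f0) / (2 * eps)
        it.iternext()
    return g
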
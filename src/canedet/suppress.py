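"""Duplicate suppression: hard NMS, linear Soft-NMS, Gaussian Shape-IoU Soft-NMS.

Dense stem nodes sit close together on a stalk, so hard thresholding throws
away genuinely distinct neighbours.  The soft variants decay the scores of
overlapping boxes instead of removing them:

* ``hard``        — greedy keep, drop everything with IoU > nt vs the kept box
* ``soft-linear`` — score ``s -> s * (1 - IoU)`` whenever IoU > nt
* ``soft-gaussian-shape`` — score ``s -> s * exp(-ShapeIoU^2 / sigma)``
  applied unconditionally, with the aspect-penalized Shape-IoU as the
  similarity so elongated near-duplicates are told apart from stacked
  distinct nodes.

All modes are greedy by descending score with deterministic tie-breaking
(larger area first, then lower original index) and operate per class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from .boxgeom import Box, BoxValidationError, iou, penalized_shape_iou

__all__ = ["Detection", "SuppressMode", "SuppressConfig",
           "nms_hard", "soft_nms_linear", "soft_nms_gaussian_shape", "suppress"]


@dataclass(frozen=True)
class Detection:
    """One scored box: the unit of suppression."""

    box: Box
    score: float
    cls: int = 0

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise BoxValidationError(f"score must lie in [0,1], got {self.score}")


class SuppressMode(str, Enum):
    HARD = "hard"
    SOFT_LINEAR = "soft-linear"
    SOFT_GAUSSIAN_SHAPE = "soft-gaussian-shape"


@dataclass(frozen=True)
class SuppressConfig:
    mode: SuppressMode = SuppressMode.SOFT_GAUSSIAN_SHAPE
    nt: float = 0.5            # overlap threshold (hard and linear modes)
    sigma: float = 0.5         # Gaussian decay scale
    score_floor: float = 1e-3  # decayed boxes below this are dropped
    alpha: float = 1.5         # aspect-penalty sharpness of the similarity

    def __post_init__(self):
        if not (0.0 < self.nt < 1.0):
            raise BoxValidationError("nt must lie in (0,1)")
        if self.sigma <= 0:
            raise BoxValidationError("sigma must be > 0")
        if not (0.0 <= self.score_floor < 1.0):
            raise BoxValidationError("score_floor must lie in [0,1)")


def _area(d: Detection) -> float:
    return float(d.box.w * d.box.h)


def _select_next(pool: list[tuple[int, Detection]]) -> int:
    """Index into pool of the current max: score desc, area desc, index asc."""
    best = 0
    for k in range(1, len(pool)):
        i, d = pool[k]
        j, m = pool[best]
        if (d.score, _area(d), -i) > (m.score, _area(m), -j):
            best = k
    return best


def _greedy(dets, decay, score_floor):
    """Shared greedy loop: ``decay(M, d) -> factor`` rescales survivors."""
    pool = list(enumerate(dets))
    kept: list[Detection] = []
    while pool:
        k = _select_next(pool)
        _, m = pool.pop(k)
        kept.append(m)
        nxt = []
        for i, d in pool:
            f = decay(m, d)
            if f >= 1.0:
                nxt.append((i, d))
                continue
            s = d.score * f
            if s > score_floor:
                nxt.append((i, replace(d, score=s)))
        pool = nxt
    return kept


def _per_class(dets, fn):
    out: list[Detection] = []
    for c in sorted({d.cls for d in dets}):
        out.extend(fn([d for d in dets if d.cls == c]))
    out.sort(key=lambda d: (-d.score, -_area(d)))
    return out


def nms_hard(dets: list[Detection], cfg: SuppressConfig | None = None) -> list[Detection]:
    """Classic greedy NMS: overlap above ``nt`` with a kept box removes a box."""
    cfg = cfg or SuppressConfig(mode=SuppressMode.HARD)

    def one_class(ds):
        def decay(m, d):
            return 0.0 if iou(m.box, d.box) > cfg.nt else 1.0
        # hard mode ignores score_floor: survivors keep their scores
        return _greedy(ds, decay, 0.0)

    return _per_class(dets, one_class)


def soft_nms_linear(dets: list[Detection], cfg: SuppressConfig | None = None) -> list[Detection]:
    """Linear Soft-NMS: ``s -> s (1 - IoU)`` for overlaps above ``nt``.

    No box is ever hard-removed for overlap alone; boxes only disappear when
    their decayed score falls to ``score_floor`` or below.
    """
    cfg = cfg or SuppressConfig(mode=SuppressMode.SOFT_LINEAR)

    def one_class(ds):
        def decay(m, d):
            v = float(iou(m.box, d.box))
            return (1.0 - v) if v > cfg.nt else 1.0
        return _greedy(ds, decay, cfg.score_floor)

    return _per_class(dets, one_class)


def soft_nms_gaussian_shape(dets: list[Detection],
                            cfg: SuppressConfig | None = None) -> list[Detection]:
    """Gaussian Soft-NMS with the aspect-penalized Shape-IoU similarity.

    Every survivor is rescaled by ``exp(-ShapeIoU(M, b)^2 / sigma)``; the
    Gaussian variant has no overlap gate, disjoint boxes simply get factor 1.
    """
    cfg = cfg or SuppressConfig(mode=SuppressMode.SOFT_GAUSSIAN_SHAPE)

    def one_class(ds):
        def decay(m, d):
            v = float(penalized_shape_iou(m.box, d.box, cfg.alpha))
            return math.exp(-(v * v) / cfg.sigma)
        return _greedy(ds, decay, cfg.score_floor)

    return _per_class(dets, one_class)


_DISPATCH = {
    SuppressMode.HARD: nms_hard,
    SuppressMode.SOFT_LINEAR: soft_nms_linear,
    SuppressMode.SOFT_GAUSSIAN_SHAPE: soft_nms_gaussian_shape,
}


def suppress(dets: list[Detection], cfg: SuppressConfig) -> list[Detection]:
    """Dispatch on ``cfg.mode``."""
    return _DISPATCH[SuppressMode(cfg.mode)](dets, cfg)
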
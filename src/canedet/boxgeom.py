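"""Axis-aligned boxes, IoU, and the Shape-IoU loss family.

Boxes live in one of three formats:

* ``center-norm``  — (xc, yc, w, h), all normalized to [0, 1] (YOLO labels)
* ``center-pixel`` — (xc, yc, w, h) in pixels (internal canonical format)
* ``corner-pixel`` — (x1, y1, x2, y2) in pixels

All geometric functions are vectorized over a trailing axis of size 4 and
work both on numpy arrays and on :class:`canedet.nn.autograd.Tensor`
objects, so the same Shape-IoU code serves as the training regression loss
and as the suppression similarity.

The Shape-IoU loss for a predicted box ``b`` against ground truth ``g``::

    loss = (1 - IoU) + dist_shape + omega_weight * Omega_shape

where ``dist_shape`` is a center-distance term whose x/y components are
weighted by the ground-truth shape (``hh`` on x, ``ww`` on y), and
``Omega_shape`` penalizes width/height gaps.  Small, elongated targets are
exactly the regime where these shape weights matter: a shift along the
short side of a thin box hurts IoU far more than the same shift along the
long side.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "BoxFormat",
    "Box",
    "GtBox",
    "ShapeIoUParams",
    "ShapeIoUResult",
    "FormatError",
    "BoxValidationError",
    "convert",
    "iou",
    "shape_weights",
    "shape_iou_loss",
    "shape_penalty",
    "penalized_shape_iou",
]

_EPS = np.finfo(np.float64).eps


class FormatError(ValueError):
    """Two boxes were combined in different coordinate formats."""


class BoxValidationError(ValueError):
    """A box violates its invariants (non-positive side, NaN, out of range)."""


class BoxFormat(str, Enum):
    CENTER_NORM = "center-norm"
    CENTER_PIXEL = "center-pixel"
    CORNER_PIXEL = "corner-pixel"


# ---------------------------------------------------------------------------
# dispatch helpers: numpy scalars/arrays vs autograd tensors
# ---------------------------------------------------------------------------

def _is_plain(x) -> bool:
    return isinstance(x, (int, float, np.ndarray, np.floating, np.integer))


def _exp(x):
    return np.exp(x) if _is_plain(x) else x.exp()


def _abs(x):
    return np.abs(x) if _is_plain(x) else x.abs()


def _maximum(a, b):
    if _is_plain(a) and _is_plain(b):
        return np.maximum(a, b)
    if not _is_plain(a):
        return a.maximum(b)
    return b.maximum(a)


def _minimum(a, b):
    if _is_plain(a) and _is_plain(b):
        return np.minimum(a, b)
    if not _is_plain(a):
        return a.minimum(b)
    return b.minimum(a)


def _relu0(x):
    """max(x, 0) for overlap widths."""
    return np.maximum(x, 0.0) if _is_plain(x) else x.maximum(0.0)


# ---------------------------------------------------------------------------
# typed single-box containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """One axis-aligned box with an explicit coordinate format."""

    xc: float
    yc: float
    w: float
    h: float
    format: BoxFormat = BoxFormat.CENTER_PIXEL

    def __post_init__(self):
        arr = np.array([self.xc, self.yc, self.w, self.h], dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            raise BoxValidationError(f"non-finite box {arr}")
        if self.format is BoxFormat.CORNER_PIXEL:
            if not (self.w > self.xc and self.h > self.yc):
                raise BoxValidationError(
                    f"corner box needs x2>x1 and y2>y1, got {arr}")
        else:
            if not (self.w > 0 and self.h > 0):
                raise BoxValidationError(f"box sides must be positive: {arr}")
            if self.format is BoxFormat.CENTER_NORM and not (
                0.0 <= self.xc <= 1.0 and 0.0 <= self.yc <= 1.0
            ):
                raise BoxValidationError(
                    f"normalized centers must lie in [0,1]: {arr}")

    def asarray(self) -> np.ndarray:
        return np.array([self.xc, self.yc, self.w, self.h], dtype=np.float64)

    def to(self, fmt: BoxFormat, image_size: tuple[int, int] | None = None) -> "Box":
        out = convert(self.asarray(), self.format, fmt, image_size)
        return Box(*out.tolist(), format=fmt)


# a ground-truth box is structurally identical; the alias keeps call
# signatures self-describing
GtBox = Box


@dataclass(frozen=True)
class ShapeIoUParams:
    """Knobs of the Shape-IoU loss.

    scale
        Exponent on the ground-truth sides in the shape weights.  At 0 the
        weights collapse to (1, 1) and the distance term reduces to the
        plain normalized center distance.
    alpha
        Sharpness of the aspect-ratio penalty ``exp(-alpha |Δaspect|)``.
    omega_weight
        Multiplier on the width/height-gap term in the total loss.
    """

    scale: float = 0.0
    alpha: float = 1.5
    omega_weight: float = 0.5

    def __post_init__(self):
        if self.scale < 0:
            raise BoxValidationError("scale must be >= 0")
        if self.alpha <= 0:
            raise BoxValidationError("alpha must be > 0")
        if self.omega_weight < 0:
            raise BoxValidationError("omega_weight must be >= 0")


@dataclass
class ShapeIoUResult:
    iou: object
    distance_shape: object
    omega_shape: object
    ww: object
    hh: object
    loss: object


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def convert(boxes, src: BoxFormat, dst: BoxFormat,
            image_size: tuple[int, int] | None = None):
    """Convert ``(..., 4)`` boxes between formats.

    ``image_size`` is (width, height) in pixels; it is required whenever a
    normalized format is involved.
    """
    src, dst = BoxFormat(src), BoxFormat(dst)
    b = np.asarray(boxes, dtype=np.float64)
    if b.shape[-1] != 4:
        raise BoxValidationError(f"boxes must have trailing size 4, got {b.shape}")
    if src == dst:
        return b.copy()

    needs_size = BoxFormat.CENTER_NORM in (src, dst)
    if needs_size and image_size is None:
        raise FormatError("image_size required to convert to/from normalized boxes")

    # to canonical center-pixel
    cp = b.copy()
    if src is BoxFormat.CENTER_NORM:
        W, H = image_size
        cp = b * np.array([W, H, W, H], dtype=np.float64)
    elif src is BoxFormat.CORNER_PIXEL:
        x1, y1, x2, y2 = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
        cp = np.stack([(x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1], axis=-1)

    if dst is BoxFormat.CENTER_PIXEL:
        return cp
    if dst is BoxFormat.CENTER_NORM:
        W, H = image_size
        return cp / np.array([W, H, W, H], dtype=np.float64)
    xc, yc, w, h = cp[..., 0], cp[..., 1], cp[..., 2], cp[..., 3]
    return np.stack([xc - w / 2, yc - h / 2, xc + w / 2, yc + h / 2], axis=-1)


def _as_cxcywh(box):
    """Accept Box | array-like | Tensor; return (xc, yc, w, h) components."""
    if isinstance(box, Box):
        if box.format is BoxFormat.CORNER_PIXEL:
            arr = convert(box.asarray(), box.format, BoxFormat.CENTER_PIXEL)
        else:
            # center-norm and center-pixel share the (xc, yc, w, h) layout
            arr = box.asarray()
        return arr[0], arr[1], arr[2], arr[3]
    if _is_plain(box):
        arr = np.asarray(box, dtype=np.float64)
        _validate_array(arr)
        return arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3]
    # autograd tensor: components via slicing, no validation possible
    return box[..., 0], box[..., 1], box[..., 2], box[..., 3]


def _validate_array(arr):
    if arr.shape[-1] != 4:
        raise BoxValidationError(f"expected trailing dim 4, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise BoxValidationError("non-finite box coordinates")
    if np.any(arr[..., 2:] <= 0):
        raise BoxValidationError("box sides must be strictly positive")


def _check_same_format(a, b):
    if isinstance(a, Box) and isinstance(b, Box) and a.format is not b.format:
        raise FormatError(f"mixed box formats: {a.format.value} vs {b.format.value}")


# ---------------------------------------------------------------------------
# IoU and the Shape-IoU family
# ---------------------------------------------------------------------------

def iou(b, g):
    """Plain intersection-over-union of center-format boxes.

    Symmetric, bounded in [0, 1], and exactly 1 only for identical boxes.
    """
    _check_same_format(b, g)
    xb, yb, wb, hb = _as_cxcywh(b)
    xg, yg, wg, hg = _as_cxcywh(g)

    lx = _maximum(xb - wb * 0.5, xg - wg * 0.5)
    rx = _minimum(xb + wb * 0.5, xg + wg * 0.5)
    ty = _maximum(yb - hb * 0.5, yg - hg * 0.5)
    by = _minimum(yb + hb * 0.5, yg + hg * 0.5)

    inter = _relu0(rx - lx) * _relu0(by - ty)
    union = wb * hb + wg * hg - inter
    return inter / _maximum(union, _EPS)


def shape_weights(g, scale: float = 0.0):
    """Ground-truth shape weights ``(ww, hh)``.

    ``ww = 2 w^s / (w^s + h^s)`` and ``hh = 2 h^s / (w^s + h^s)`` computed on
    the ground-truth sides; they always sum to 2 and collapse to (1, 1) for
    a square gt or at ``scale = 0``.
    """
    _, _, wg, hg = _as_cxcywh(g)
    ws = wg ** scale
    hs = hg ** scale
    denom = ws + hs
    return 2.0 * ws / denom, 2.0 * hs / denom


def shape_iou_loss(b, g, params: ShapeIoUParams | None = None, c2=None):
    """Shape-IoU regression loss of predicted box ``b`` against gt ``g``.

    ``c2`` is the squared diagonal of the smallest box enclosing both; it is
    computed internally when not given (the parameter exists so tests can
    pin it).  Returns a :class:`ShapeIoUResult`; ``loss`` is differentiable
    w.r.t. ``b`` when ``b`` is an autograd tensor.
    """
    p = params or ShapeIoUParams()
    _check_same_format(b, g)
    xb, yb, wb, hb = _as_cxcywh(b)
    xg, yg, wg, hg = _as_cxcywh(g)

    ww, hh = shape_weights(g, p.scale)
    i = iou(b, g)

    if c2 is None:
        ex = _maximum(xb + wb * 0.5, xg + wg * 0.5) - _minimum(xb - wb * 0.5, xg - wg * 0.5)
        ey = _maximum(yb + hb * 0.5, yg + hg * 0.5) - _minimum(yb - hb * 0.5, yg - hg * 0.5)
        c2 = ex * ex + ey * ey
    c2 = _maximum(c2, _EPS)

    dx = xb - xg
    dy = yb - yg
    dist = (hh * dx * dx + ww * dy * dy) / c2

    # width/height gap terms; the y-weight ww multiplies the height gap and
    # the x-weight hh the width gap (mirroring the distance weighting)
    om_w = hh * _abs(wb - wg) / _maximum(wb, wg)
    om_h = ww * _abs(hb - hg) / _maximum(hb, hg)
    one = 1.0
    omega = (one - _exp(0.0 - om_w)) ** 4 + (one - _exp(0.0 - om_h)) ** 4

    loss = (1.0 - i) + dist + p.omega_weight * omega
    return ShapeIoUResult(iou=i, distance_shape=dist, omega_shape=omega,
                          ww=ww, hh=hh, loss=loss)


def shape_penalty(b, g, alpha: float = 1.5):
    """Aspect-ratio agreement factor ``exp(-alpha |w/h - w_gt/h_gt|)``.

    Equals 1 for matching aspect ratios and decays monotonically with the
    aspect gap; always in (0, 1].
    """
    if alpha <= 0:
        raise BoxValidationError("alpha must be > 0")
    _check_same_format(b, g)
    _, _, wb, hb = _as_cxcywh(b)
    _, _, wg, hg = _as_cxcywh(g)
    gap = _abs(wb / hb - wg / hg)
    return _exp(0.0 - alpha * gap)


def penalized_shape_iou(b, g, alpha: float = 1.5):
    """IoU multiplied by the aspect penalty: the suppression similarity.

    Never exceeds plain IoU; equality holds exactly when the two aspect
    ratios agree.
    """
    return iou(b, g) * shape_penalty(b, g, alpha)
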
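"""Synthetic sugarcane stem-node scenes with YOLO-format labels.

The generator emulates the statistical structure of field imagery of
sugarcane: several roughly vertical, textured stalks per frame; each stalk
carries a series of short, wide, brighter transverse bands (the stem
nodes — the single detection class); leaves partially occlude some nodes;
illumination varies smoothly across the frame.  Three extreme-condition
augmentations (dust, rain, strong light) stress-test robustness without
touching the geometry, so labels survive augmentation unchanged.

It makes no attempt at photorealism: its job is to give every downstream
component (loss, suppression, neck/head, pruning, evaluator) a target
distribution with the right *shape* — dense, small, elongated, partially
occluded bright bands on vertical stalks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from .boxgeom import Box, BoxFormat, BoxValidationError

__all__ = ["SceneConfig", "AugmentRegime", "generate_scene", "augment",
           "make_dataset", "load_dataset", "size_bin", "SIZE_BIN_CUTOFFS"]

# COCO-style area cutoffs (pixels^2) separating small / medium / large boxes
SIZE_BIN_CUTOFFS = (32.0 ** 2, 96.0 ** 2)


@dataclass(frozen=True)
class SceneConfig:
    """Layout and appearance of one synthetic scene.

    Ranges are inclusive (low, high) and sampled uniformly.  ``node_aspect``
    is width/height of the node band: stem nodes are wider than tall, which
    is exactly the elongation the shape-aware loss targets.
    """

    image_size: int = 640
    n_stalks: tuple[int, int] = (3, 6)
    nodes_per_stalk: tuple[int, int] = (3, 7)
    stalk_width_frac: tuple[float, float] = (0.025, 0.2)
    node_aspect: tuple[float, float] = (1.5, 4.0)
    occlusion_prob: float = 0.3
    illumination: float = 0.35
    seed: int = 0

    def __post_init__(self):
        for r in (self.n_stalks, self.nodes_per_stalk,
                  self.stalk_width_frac, self.node_aspect):
            if r[1] < r[0]:
                raise BoxValidationError(f"empty range {r}")
        if not (0.0 <= self.occlusion_prob <= 1.0):
            raise BoxValidationError("occlusion_prob must lie in [0,1]")


@dataclass(frozen=True)
class AugmentRegime:
    """One extreme-condition augmentation: dust, rain or strong_light."""

    kind: str
    intensity: float = 0.5

    _KINDS = ("dust", "rain", "strong_light")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise BoxValidationError(
                f"unknown augmentation {self.kind!r}; choose from {self._KINDS}")
        if not (0.0 <= self.intensity <= 1.0):
            raise BoxValidationError("intensity must lie in [0,1]")


def _smooth_noise(rng, shape, sigma, lo=0.0, hi=1.0):
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    n = (n - n.min()) / max(float(np.ptp(n)), 1e-9)
    return lo + (hi - lo) * n


def generate_scene(cfg: SceneConfig, with_masks: bool = False):
    """Render one scene.

    Returns ``(image, boxes)`` — uint8 HxWx3 image and a list of
    ground-truth :class:`~canedet.boxgeom.Box` in center-pixel format — or
    ``(image, boxes, masks)`` with one boolean band mask per node when
    ``with_masks`` is set.  Deterministic for a fixed config (the seed is
    part of the config).
    """
    rng = np.random.default_rng(cfg.seed)
    S = cfg.image_size
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)

    # --- background: textured soil/foliage with an illumination gradient
    img = np.empty((S, S, 3), dtype=np.float64)
    base = np.array([98.0, 112.0, 72.0])  # muted green-brown
    tex = _smooth_noise(rng, (S, S), S / 40.0, -18.0, 18.0)
    for c in range(3):
        img[..., c] = base[c] + tex + rng.standard_normal((S, S)) * 6.0

    ang = rng.uniform(0, 2 * np.pi)
    grad = (np.cos(ang) * (xx / S - 0.5) + np.sin(ang) * (yy / S - 0.5))
    img *= (1.0 + cfg.illumination * grad)[..., None]

    # --- stalks with node bands
    n_stalks = int(rng.integers(cfg.n_stalks[0], cfg.n_stalks[1] + 1))
    boxes: list[Box] = []
    masks: list[np.ndarray] = []
    occluders = []

    for _ in range(n_stalks):
        x0 = rng.uniform(0.05 * S, 0.95 * S)
        slope = rng.uniform(-0.08, 0.08)          # nearly vertical
        w = rng.uniform(*cfg.stalk_width_frac) * S
        center = x0 + slope * (yy - S / 2.0)
        inside = np.abs(xx - center) < w / 2.0

        stalk_col = np.array([150.0, 140.0, 70.0]) + rng.uniform(-18, 18, 3)
        # cylindrical shading: darker near the edges, vertical streak texture
        lateral = np.clip(1.0 - (np.abs(xx - center) / (w / 2.0 + 1e-9)) ** 2, 0.0, 1.0)
        streak = 1.0 + 0.08 * np.sin(yy / max(2.0, w / 3.0) + rng.uniform(0, 6.28))
        shade = (0.55 + 0.45 * lateral) * streak
        for c in range(3):
            img[..., c] = np.where(inside, stalk_col[c] * shade, img[..., c])

        # node bands spaced along the stalk
        n_nodes = int(rng.integers(cfg.nodes_per_stalk[0], cfg.nodes_per_stalk[1] + 1))
        ys = np.sort(rng.uniform(0.06 * S, 0.94 * S, n_nodes))
        band_w = w * 1.08
        for yn in ys:
            aspect = rng.uniform(*cfg.node_aspect)
            band_h = band_w / aspect
            band = (np.abs(xx - center) < band_w / 2.0) & (np.abs(yy - yn) < band_h / 2.0)
            if not band.any():
                continue
            glow = np.array([208.0, 190.0, 120.0]) + rng.uniform(-10, 10, 3)
            ring = np.abs(yy - yn) < band_h * 0.12
            for c in range(3):
                img[..., c] = np.where(band, glow[c] * (0.75 + 0.25 * lateral), img[..., c])
                img[..., c] = np.where(band & ring, glow[c] * 0.55, img[..., c])
            ys_pix, xs_pix = np.nonzero(band)
            x1, x2 = xs_pix.min(), xs_pix.max() + 1
            y1, y2 = ys_pix.min(), ys_pix.max() + 1
            boxes.append(Box((x1 + x2) / 2.0, (y1 + y2) / 2.0,
                             float(x2 - x1), float(y2 - y1),
                             format=BoxFormat.CENTER_PIXEL))
            if with_masks:
                masks.append(band)
            if rng.uniform() < cfg.occlusion_prob:
                occluders.append((float(np.clip((x1 + x2) / 2 + rng.uniform(-w, w), 0, S - 1)),
                                  float(yn + rng.uniform(-band_h, band_h)),
                                  float(rng.uniform(0.4, 1.1) * band_w),
                                  float(rng.uniform(0.25, 0.6) * band_w),
                                  float(rng.uniform(0, np.pi))))

    # --- leaf occluders drawn last: labels are NOT trimmed by occlusion,
    #     matching how partially hidden nodes are annotated in practice
    for (ox, oy, a, b, th) in occluders:
        xr = (xx - ox) * np.cos(th) + (yy - oy) * np.sin(th)
        yr = -(xx - ox) * np.sin(th) + (yy - oy) * np.cos(th)
        leaf = (xr / max(a, 1e-9)) ** 2 + (yr / max(b, 1e-9)) ** 2 < 1.0
        leaf_col = np.array([70.0, 128.0, 52.0]) + rng.uniform(-12, 12, 3)
        for c in range(3):
            img[..., c] = np.where(leaf, leaf_col[c], img[..., c])

    out = np.clip(img, 0, 255).astype(np.uint8)
    if with_masks:
        return out, boxes, masks
    return out, boxes


def augment(image: np.ndarray, regime: AugmentRegime, seed: int = 0) -> np.ndarray:
    """Apply one extreme-condition augmentation; geometry is untouched.

    ``intensity == 0`` is the exact identity.
    """
    if regime.intensity == 0.0:
        return image.copy()
    rng = np.random.default_rng(seed)
    t = regime.intensity
    img = image.astype(np.float64)
    S0, S1 = img.shape[:2]

    if regime.kind == "dust":
        # low-contrast particulate haze: pull toward a dusty tone, add
        # soft blobs and fine speckle
        haze = np.array([188.0, 172.0, 140.0])
        img = (1 - 0.55 * t) * img + 0.55 * t * haze
        blobs = _smooth_noise(rng, (S0, S1), S0 / 24.0, -1.0, 1.0)
        img += (22.0 * t * blobs)[..., None]
        speck = (rng.uniform(size=(S0, S1)) < 0.004 * t)
        img[speck] = np.clip(img[speck] + 60.0, 0, 255)
    elif regime.kind == "rain":
        # translucent diagonal streaks plus slight vertical smear
        streaks = np.zeros((S0, S1))
        n = int(60 * t * (S0 * S1) / (640 * 640) + 1)
        for _ in range(max(n, 8)):
            x = rng.uniform(0, S1)
            y = rng.uniform(0, S0)
            length = rng.uniform(0.05, 0.18) * S0
            dx = rng.uniform(-0.25, 0.25)
            steps = np.arange(int(length))
            xs = np.clip((x + dx * steps).astype(int), 0, S1 - 1)
            ys = np.clip((y + steps).astype(int), 0, S0 - 1)
            streaks[ys, xs] = 1.0
        streaks = ndimage.gaussian_filter(streaks, 0.8)
        k = max(int(3 + 6 * t), 3)
        kernel = np.zeros((k, 1))
        kernel[:, 0] = 1.0 / k
        for c in range(3):
            img[..., c] = ndimage.convolve(img[..., c], kernel, mode="nearest")
        img += (70.0 * t * streaks)[..., None]
    else:  # strong_light
        yy, xx = np.mgrid[0:S0, 0:S1].astype(np.float64)
        cx, cy = rng.uniform(0.2, 0.8) * S1, rng.uniform(0.0, 0.4) * S0
        r2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (0.5 * max(S0, S1)) ** 2
        highlight = np.exp(-r2)
        img += (160.0 * t * highlight)[..., None]
        img = img * (1.0 + 0.25 * t)  # overall exposure push, then clip

    return np.clip(img, 0, 255).astype(np.uint8)


def size_bin(area: float) -> str:
    """COCO-style small/medium/large membership from pixel area."""
    if area < SIZE_BIN_CUTOFFS[0]:
        return "small"
    if area < SIZE_BIN_CUTOFFS[1]:
        return "medium"
    return "large"


def make_dataset(n_images: int, cfg: SceneConfig, out_dir,
                 split_ratio: float = 0.8, seed: int | None = None) -> dict:
    """Write a YOLO-layout dataset and return (and save) its manifest.

    Layout: ``images/{train,val}/*.png`` and ``labels/{train,val}/*.txt``
    with one ``cls xc yc w h`` line per box (normalized), plus
    ``manifest.yaml`` recording the split, per-box size-bin membership and
    a content hash for reproducibility checks.
    """
    out = Path(out_dir)
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_images)
    n_train = int(round(n_images * split_ratio))
    split_of = {int(order[i]): ("train" if i < n_train else "val")
                for i in range(n_images)}

    for sub in ("images/train", "images/val", "labels/train", "labels/val"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    manifest = {"seed": int(seed), "image_size": cfg.image_size,
                "split_ratio": split_ratio, "classes": ["stem_node"],
                "images": []}
    hasher = hashlib.sha256()
    for i in range(n_images):
        scfg = SceneConfig(**{**cfg.__dict__, "seed": seed + 1000 + i})
        img, boxes = generate_scene(scfg)
        split = split_of[i]
        name = f"img_{i:04d}"
        Image.fromarray(img).save(out / "images" / split / f"{name}.png")
        lines = []
        bins = []
        for b in boxes:
            xc, yc, w, h = (b.xc / cfg.image_size, b.yc / cfg.image_size,
                            b.w / cfg.image_size, b.h / cfg.image_size)
            lines.append(f"0 {xc:.6f} {yc:.6f} {w:.6f} {h:.6f}")
            bins.append(size_bin(b.w * b.h))
        label_text = "\n".join(lines) + ("\n" if lines else "")
        (out / "labels" / split / f"{name}.txt").write_text(label_text)
        hasher.update(img.tobytes())
        hasher.update(label_text.encode())
        manifest["images"].append({"name": name, "split": split,
                                   "n_boxes": len(boxes), "size_bins": bins})
    manifest["content_sha256"] = hasher.hexdigest()
    with open(out / "manifest.yaml", "w") as f:
        yaml.safe_dump(manifest, f, sort_keys=False)
    return manifest


def load_dataset(root) -> dict:
    """Read back a dataset written by :func:`make_dataset`.

    Returns ``{"train": [(image, boxes_pixel), ...], "val": [...],
    "manifest": ...}`` with boxes as center-pixel :class:`Box`.
    """
    root = Path(root)
    with open(root / "manifest.yaml") as f:
        manifest = yaml.safe_load(f)
    S = manifest["image_size"]
    out = {"train": [], "val": [], "manifest": manifest}
    for rec in manifest["images"]:
        split, name = rec["split"], rec["name"]
        img = np.asarray(Image.open(root / "images" / split / f"{name}.png"))
        boxes = []
        for line in (root / "labels" / split / f"{name}.txt").read_text().splitlines():
            if not line.strip():
                continue
            _, xc, yc, w, h = line.split()
            boxes.append(Box(float(xc) * S, float(yc) * S,
                             float(w) * S, float(h) * S,
                             format=BoxFormat.CENTER_PIXEL))
        out[split].append((img, boxes))
    return out
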
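"""Synthetic fused PET-CT-like detection fixtures.

Emulates the statistical structure of a 15-class lymph-node dataset — a
grayscale torso-like anatomical background with bright warm-colormap
"uptake" ellipses whose image zone determines the class — so every other
module is testable without the private clinical deposit.  The appearance
model is deliberately non-clinical: it reproduces class geometry, balanced
counts (168 images per class, the normal class at 170) and deliberately
rare classes (nose 14, retroperitoneal 9 instances), not radiology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .arch import CLASS_NAMES
from .data import (BoundingBox, LabeledImage, write_yolo_labels,
                   write_dataset_descriptor)

# Anatomical zone centers (cx, cy fractions; "rt" = patient right = image left)
DEFAULT_ZONES = {
    "abdominal":        (0.50, 0.60),
    "cervical":         (0.50, 0.12),
    "lt-subclavicular": (0.63, 0.22),
    "lt-inguinal":      (0.60, 0.88),
    "mediastinal":      (0.50, 0.36),
    "normal":           (0.20, 0.48),
    "nose":             (0.50, 0.04),
    "pelvis":           (0.50, 0.77),
    "retroperitoneal":  (0.40, 0.62),
    "rt-cervical":      (0.38, 0.13),
    "rt-subclavicular": (0.37, 0.22),
    "rt-axillary":      (0.28, 0.32),
    "rt-inguinal":      (0.40, 0.88),
    "lt-axillary":      (0.72, 0.32),
    "lt-cervical":      (0.62, 0.13),
}

# left/right station pairs (for the confusability knob)
PAIRED_ZONES = [("lt-subclavicular", "rt-subclavicular"),
                ("lt-inguinal", "rt-inguinal"),
                ("lt-cervical", "rt-cervical"),
                ("lt-axillary", "rt-axillary")]

# Characteristic ellipse aspect (width/height) per anatomical station.
# Left/right stations share their base station's shape, so paired classes
# stay distinguishable by position only — the axis the confusability knob
# (:func:`degrade`) manipulates.
STATION_ASPECT = {
    "abdominal": 1.0, "cervical": 1.6, "subclavicular": 1.3, "inguinal": 0.6,
    "mediastinal": 1.15, "normal": 0.85, "nose": 0.7, "pelvis": 1.45,
    "retroperitoneal": 0.75,  "axillary": 0.55,
}


def _station_aspect(cls_name: str) -> float:
    base = cls_name
    for prefix in ("lt-", "rt-"):
        if base.startswith(prefix):
            base = base[len(prefix):]
    return STATION_ASPECT.get(base, 1.0)


def default_class_counts() -> dict[str, int]:
    counts = {name: 168 for name in CLASS_NAMES}
    counts["normal"] = 170
    counts["nose"] = 14
    counts["retroperitoneal"] = 9
    return counts


@dataclass
class FixtureConfig:
    image_size: int = 640
    class_names: list = field(default_factory=lambda: list(CLASS_NAMES))
    per_class_counts: dict = field(default_factory=default_class_counts)
    boxes_per_image: tuple = (1, 3)
    blob_size_range: tuple = (0.06, 0.14)   # ellipse semi-size as image fraction
    noise_sd: float = 8.0                   # background noise, 8-bit units
    seed: int = 0
    zones: dict = field(default_factory=lambda: dict(DEFAULT_ZONES))
    zone_jitter: float = 0.03

    def __post_init__(self):
        if not all(v >= 0 for v in self.per_class_counts.values()):
            raise ValueError("class counts must be nonnegative")
        lo, hi = self.blob_size_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("blob sizes must lie in (0, 0.5]")
        b0, b1 = self.boxes_per_image
        if not 1 <= b0 <= b1 <= 3:
            raise ValueError("boxes_per_image must lie in 1..3")


def rare_class_config(image_size: int = 64, seed: int = 0,
                      common_count: int = 50) -> FixtureConfig:
    """A desk-scale set reproducing the rare-class failure mode.

    Four common stations at ``common_count`` images each against the two
    deliberately rare classes at their real-data instance counts (nose 14,
    retroperitoneal 9, the latter sharing the abdominal zone region).
    """
    names = ["abdominal", "cervical", "lt-inguinal", "lt-axillary",
             "nose", "retroperitoneal"]
    counts = {n: common_count for n in names}
    counts["nose"] = 14
    counts["retroperitoneal"] = 9
    return FixtureConfig(image_size=image_size, class_names=names,
                         per_class_counts=counts, boxes_per_image=(1, 1),
                         blob_size_range=(0.12, 0.18), noise_sd=6.0,
                         zone_jitter=0.05, seed=seed)


def easy_two_class_config(n_images: int = 200, image_size: int = 64,
                          seed: int = 0) -> FixtureConfig:
    """An easy benchmark set: two well-separated classes, one large blob each."""
    per = n_images // 2
    return FixtureConfig(
        image_size=image_size,
        class_names=["cervical", "lt-inguinal"],
        per_class_counts={"cervical": per, "lt-inguinal": n_images - per},
        boxes_per_image=(1, 1),
        blob_size_range=(0.14, 0.2),
        noise_sd=6.0,
        zones={"cervical": (0.5, 0.2), "lt-inguinal": (0.62, 0.8)},
        zone_jitter=0.1,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------------

def _background(size: int, rng: np.random.Generator, noise_sd: float
                ) -> np.ndarray:
    """Grayscale torso-like ellipse on a dark field plus Gaussian noise."""
    yy, xx = np.mgrid[0:size, 0:size] / size
    body = (((xx - 0.5) / 0.38) ** 2 + ((yy - 0.5) / 0.47) ** 2) <= 1.0
    img = np.full((size, size), 18.0)
    img[body] = 70.0
    img += 18.0 * np.exp(-(((xx - 0.5) / 0.18) ** 2 + ((yy - 0.45) / 0.3) ** 2))
    img += rng.normal(0.0, noise_sd, (size, size))
    gray = np.clip(img, 0, 255)
    return np.repeat(gray[..., None], 3, axis=2)


def _paint_uptake(img: np.ndarray, cx: float, cy: float, rx: float, ry: float,
                  rng: np.random.Generator):
    """Warm-colormap elliptical 'uptake' blob with a soft falloff."""
    size = img.shape[0]
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (((xx - cx * size) / (rx * size)) ** 2
          + ((yy - cy * size) / (ry * size)) ** 2)
    hot = np.clip(1.0 - d2, 0.0, 1.0) ** 0.7
    peak = rng.uniform(200.0, 255.0)
    img[..., 0] = np.clip(img[..., 0] + hot * peak, 0, 255)            # red
    img[..., 1] = np.clip(img[..., 1] + hot * peak * 0.65, 0, 255)     # yellow tint
    img[..., 2] = np.clip(img[..., 2] - hot * 25.0, 0, 255)


def _place_instance(cls_name: str, cfg: FixtureConfig,
                    rng: np.random.Generator, existing: list[BoundingBox],
                    class_id: int) -> BoundingBox | None:
    zx, zy = cfg.zones[cls_name]
    lo, hi = cfg.blob_size_range
    aspect = _station_aspect(cls_name)
    for _ in range(100):
        r = rng.uniform(lo, hi)
        jitter = rng.uniform(0.9, 1.1)
        rx = float(np.clip(r * np.sqrt(aspect) * jitter, 0.8 * lo, 1.25 * hi))
        ry = float(np.clip(r / np.sqrt(aspect) / jitter, 0.8 * lo, 1.25 * hi))
        cx = float(np.clip(zx + rng.normal(0, cfg.zone_jitter), rx + 0.01,
                           1 - rx - 0.01))
        cy = float(np.clip(zy + rng.normal(0, cfg.zone_jitter), ry + 0.01,
                           1 - ry - 0.01))
        cand = BoundingBox(class_id, cx, cy, 2 * rx, 2 * ry)
        if all(_iou_norm(cand, b) < 0.25 for b in existing):
            return cand
    return None


def _iou_norm(a: BoundingBox, b: BoundingBox) -> float:
    ax1, ay1, ax2, ay2 = a.to_xyxy()
    bx1, by1, bx2, by2 = b.to_xyxy()
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a.area() + b.area() - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_records(cfg: FixtureConfig):
    """Generate the dataset in memory.

    Returns (records, images): LabeledImage list and id -> uint8 HxWx3 array.
    Total label lines equal the summed per-class instance counts (up to
    instances skipped after 100 failed placements, which are logged on the
    record of the manifest).
    """
    rng = np.random.default_rng(cfg.seed)
    name_to_id = {n: i for i, n in enumerate(cfg.class_names)}
    pool = []
    for name, count in cfg.per_class_counts.items():
        pool.extend([name] * int(count))
    pool = [pool[i] for i in rng.permutation(len(pool))]

    records, images = [], {}
    idx = 0
    b_lo, b_hi = cfg.boxes_per_image
    skipped = 0
    while pool:
        n_obj = int(rng.integers(b_lo, b_hi + 1))
        group, pool = pool[:n_obj], pool[n_obj:]
        img = _background(cfg.image_size, rng, cfg.noise_sd)
        boxes: list[BoundingBox] = []
        for cls_name in group:
            box = _place_instance(cls_name, cfg, rng, boxes,
                                  name_to_id[cls_name])
            if box is None:
                skipped += 1
                continue
            rx, ry = box.w / 2, box.h / 2
            _paint_uptake(img, box.cx, box.cy, rx, ry, rng)
            boxes.append(box)
        image_id = f"syn_{idx:05d}"
        idx += 1
        records.append(LabeledImage(image_id=image_id,
                                    width=cfg.image_size, height=cfg.image_size,
                                    boxes=boxes))
        images[image_id] = img.astype(np.uint8)
    if skipped:
        import logging
        logging.getLogger(__name__).warning(
            "skipped %d instances after 100 placement attempts", skipped)
    return records, images


def generate_dataset(cfg: FixtureConfig, out_dir: str | Path) -> dict:
    """Write the standard YOLO layout plus a JSON instance-count manifest."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    records, images = generate_records(cfg)
    per_class = {n: 0 for n in cfg.class_names}
    for rec in records:
        Image.fromarray(images[rec.image_id]).save(
            out / "images" / f"{rec.image_id}.png")
        (out / "labels" / f"{rec.image_id}.txt").write_text(
            write_yolo_labels(rec.boxes))
        rec.path = str(out / "images" / f"{rec.image_id}.png")
        for b in rec.boxes:
            per_class[cfg.class_names[b.class_id]] += 1
    manifest = {"n_images": len(records),
                "image_size": cfg.image_size,
                "seed": cfg.seed,
                "class_names": list(cfg.class_names),
                "per_class_instances": per_class}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    write_dataset_descriptor(out / "dataset.yaml", cfg.class_names, root=out)
    return manifest


def degrade(cfg: FixtureConfig, overlap_level: float) -> FixtureConfig:
    """Move paired left/right class zones toward each other.

    ``overlap_level`` 0 leaves the dataset unchanged; 1 makes paired zone
    centers coincide at their midpoint.  Labels are unaffected.
    """
    if not 0.0 <= overlap_level <= 1.0:
        raise ValueError("overlap_level must lie in [0, 1]")
    zones = dict(cfg.zones)
    for left, right in PAIRED_ZONES:
        if left in zones and right in zones:
            lx, ly = zones[left]
            rx, ry = zones[right]
            mx, my = (lx + rx) / 2, (ly + ry) / 2
            t = overlap_level
            zones[left] = (lx + (mx - lx) * t, ly + (my - ly) * t)
            zones[right] = (rx + (mx - rx) * t, ry + (my - ry) * t)
    out = FixtureConfig(**{**cfg.__dict__, "zones": zones})
    return out
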
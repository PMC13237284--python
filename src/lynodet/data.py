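"""YOLO-format detection datasets: label I/O, splits, augmentation, leakage audit.

Labels follow the darknet text convention: one line per object, `class cx cy
w h` with center/size normalized to [0, 1] (a sixth column holds confidence
for prediction files).  The split and augmentation protocol is
leakage-controlled: augmentation applies only to training records, every
augmented record carries provenance back to its origin image, and an auditor
verifies that no derivative of a validation or test image can reach training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

NUM_CLASSES = 15


class LabelFormatError(ValueError):
    pass


class LeakageError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Boxes and records
# ---------------------------------------------------------------------------

@dataclass
class BoundingBox:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    conf: float | None = None

    def clipped(self, tol: float = 1e-6) -> "BoundingBox":
        """Clip the box to the unit square, preserving its center ordering."""
        x1 = max(0.0, self.cx - self.w / 2)
        y1 = max(0.0, self.cy - self.h / 2)
        x2 = min(1.0, self.cx + self.w / 2)
        y2 = min(1.0, self.cy + self.h / 2)
        return BoundingBox(self.class_id, (x1 + x2) / 2, (y1 + y2) / 2,
                           max(x2 - x1, 0.0), max(y2 - y1, 0.0), self.conf)

    def to_xyxy(self, width: float = 1.0, height: float = 1.0):
        return np.array([(self.cx - self.w / 2) * width,
                         (self.cy - self.h / 2) * height,
                         (self.cx + self.w / 2) * width,
                         (self.cy + self.h / 2) * height])

    def area(self) -> float:
        return self.w * self.h


@dataclass
class Provenance:
    origin_id: str
    ops: list = field(default_factory=list)

    @property
    def is_original(self) -> bool:
        return not self.ops


@dataclass
class LabeledImage:
    image_id: str
    path: str | None = None
    width: int = 0
    height: int = 0
    boxes: list = field(default_factory=list)
    split: str | None = None
    provenance: Provenance | None = None

    def __post_init__(self):
        if self.provenance is None:
            self.provenance = Provenance(origin_id=self.image_id)
        if self.provenance.ops and self.split not in (None, "train"):
            raise LeakageError(
                f"augmented record {self.image_id} may only carry split=train, "
                f"got {self.split!r}")

    @property
    def first_class(self) -> int:
        return self.boxes[0].class_id if self.boxes else -1


# ---------------------------------------------------------------------------
# Label text I/O
# ---------------------------------------------------------------------------

def read_yolo_labels(label_text: str, num_classes: int = NUM_CLASSES,
                     strict: bool = False) -> list[BoundingBox]:
    """Parse darknet label text.  Empty text -> empty list (background image)."""
    boxes = []
    for ln, line in enumerate(label_text.splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (5, 6):
            raise LabelFormatError(f"line {ln}: expected 5 or 6 fields, "
                                   f"got {len(parts)}")
        try:
            cid = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as e:
            raise LabelFormatError(f"line {ln}: {e}") from None
        if not 0 <= cid < num_classes:
            raise LabelFormatError(f"line {ln}: class id {cid} outside "
                                   f"[0, {num_classes})")
        conf = vals[4] if len(vals) == 5 else None
        box = BoundingBox(cid, *vals[:4], conf=conf)
        out_of_range = (box.cx - box.w / 2 < -1e-6 or box.cx + box.w / 2 > 1 + 1e-6
                        or box.cy - box.h / 2 < -1e-6 or box.cy + box.h / 2 > 1 + 1e-6)
        if out_of_range:
            if strict:
                raise LabelFormatError(f"line {ln}: box extends outside the "
                                       f"unit square")
            box = box.clipped()
        boxes.append(box)
    return boxes


def write_yolo_labels(boxes: list[BoundingBox]) -> str:
    """Serialize boxes at 6-decimal precision (lossless round-trip)."""
    lines = []
    for b in boxes:
        line = f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
        if b.conf is not None:
            line += f" {b.conf:.6f}"
        lines.append(line)
    return "\n".join(lines) + ("\n" if lines else "")


def load_dataset_dir(root: str | Path, num_classes: int = NUM_CLASSES
                     ) -> list[LabeledImage]:
    """Read a YOLO layout: images/*.png|jpg with labels/*.txt by stem."""
    root = Path(root)
    records = []
    for img_path in sorted((root / "images").glob("*")):
        if img_path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        lbl = root / "labels" / (img_path.stem + ".txt")
        text = lbl.read_text() if lbl.exists() else ""
        with Image.open(img_path) as im:
            w, h = im.size
        records.append(LabeledImage(image_id=img_path.stem, path=str(img_path),
                                    width=w, height=h,
                                    boxes=read_yolo_labels(text, num_classes)))
    return records


# ---------------------------------------------------------------------------
# Split manifests
# ---------------------------------------------------------------------------

@dataclass
class SplitManifest:
    scheme: str
    seed: int
    assignment: dict          # image_id -> split name
    class_counts: dict = field(default_factory=dict)
    fold: int | None = None

    def ids(self, split: str) -> list[str]:
        return sorted(i for i, s in self.assignment.items() if s == split)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SplitManifest":
        return cls(**json.loads(text))

    def save(self, path):
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SplitManifest":
        return cls.from_json(Path(path).read_text())


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [n * f for f in fractions]
    base = [int(x) for x in raw]
    rem = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def split_holdout(ids, fractions=(0.8, 0.1, 0.1), seed: int = 0,
                  key_by: dict | None = None) -> SplitManifest:
    """Stratified train/val/test hold-out with largest-remainder rounding.

    ``key_by`` maps id -> stratum (the class of the image's first box); when
    omitted all ids form one stratum.
    """
    ids = list(ids)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(ids) < len(fractions):
        raise ValueError(f"need at least {len(fractions)} ids, got {len(ids)}")
    names = ["train", "val", "test"][: len(fractions)]
    rng = np.random.default_rng(seed)
    targets = _largest_remainder(len(ids), fractions)

    strata: dict = {}
    for i in ids:
        strata.setdefault(key_by.get(i) if key_by else 0, []).append(i)

    assignment: dict[str, str] = {}
    filled = [0] * len(names)
    for key in sorted(strata, key=str):
        members = sorted(strata[key])
        rng.shuffle(members)
        alloc = _largest_remainder(len(members), fractions)
        pos = 0
        for si, cnt in enumerate(alloc):
            for m in members[pos: pos + cnt]:
                assignment[m] = names[si]
            filled[si] += cnt
            pos += cnt
    # reconcile per-stratum rounding drift against the global targets
    for si in range(len(names)):
        while filled[si] > targets[si]:
            di = int(np.argmin(np.array(filled) - np.array(targets)))
            movable = [i for i, s in assignment.items() if s == names[si]]
            mv = movable[int(rng.integers(len(movable)))]
            assignment[mv] = names[di]
            filled[si] -= 1
            filled[di] += 1

    counts = {n: {} for n in names}
    if key_by:
        for i, s in assignment.items():
            k = str(key_by.get(i))
            counts[s][k] = counts[s].get(k, 0) + 1
    else:
        for n in names:
            counts[n] = {"all": sum(1 for s in assignment.values() if s == n)}
    return SplitManifest(scheme="holdout_" + "_".join(str(int(f * 100))
                                                      for f in fractions),
                         seed=seed, assignment=assignment, class_counts=counts)


def split_kfold(ids, k: int = 5, seed: int = 0,
                key_by: dict | None = None) -> list[SplitManifest]:
    """Stratified k-fold: one manifest per fold; each id validates once.

    Items are dealt round-robin within a single pass over shuffled strata, so
    fold sizes differ by at most one both globally and per class.
    """
    ids = list(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} ids")
    rng = np.random.default_rng(seed)
    strata: dict = {}
    for i in ids:
        strata.setdefault(key_by.get(i) if key_by else 0, []).append(i)
    fold_of: dict[str, int] = {}
    cursor = int(rng.integers(k))
    for key in sorted(strata, key=str):
        members = sorted(strata[key])
        rng.shuffle(members)
        for m in members:
            fold_of[m] = cursor % k
            cursor += 1
    manifests = []
    for f in range(k):
        assignment = {i: ("val" if fold_of[i] == f else "train") for i in ids}
        counts: dict = {"train": {}, "val": {}}
        if key_by:
            for i, s in assignment.items():
                ck = str(key_by.get(i))
                counts[s][ck] = counts[s].get(ck, 0) + 1
        manifests.append(SplitManifest(scheme=f"kfold_{k}", seed=seed,
                                       assignment=assignment,
                                       class_counts=counts, fold=f))
    return manifests


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

ALLOWED_OPS = ("hflip", "vflip", "rot+45", "rot-45", "brightness", "zoom")
_MIN_AREA_SURVIVAL = 0.10    # drop boxes losing >90% of area to frame clipping


def _rotate_boxes(boxes, angle_deg: float) -> list[BoundingBox]:
    """Axis-aligned re-enclosure of box corners rotated about image center.

    Image content rotates counterclockwise on screen by ``angle_deg``; with
    y pointing down this moves a point p to c + R(-a)(p - c).
    """
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    out = []
    for b in boxes:
        x1, y1, x2, y2 = b.to_xyxy()
        corners = np.array([[x1, y1], [x2, y1], [x2, y2], [x1, y2]]) - 0.5
        rc = corners @ rot.T + 0.5
        nx1, ny1 = rc.min(axis=0)
        nx2, ny2 = rc.max(axis=0)
        enclosed = BoundingBox(b.class_id, (nx1 + nx2) / 2, (ny1 + ny2) / 2,
                               nx2 - nx1, ny2 - ny1)
        clipped = enclosed.clipped()
        if enclosed.area() > 0 and clipped.area() / enclosed.area() >= _MIN_AREA_SURVIVAL:
            out.append(clipped)
    return out


def augment_record(image: np.ndarray, boxes: list[BoundingBox], ops,
                   rng: np.random.Generator | None = None):
    """Apply geometric/photometric ops to an image and its labels.

    ``ops`` is a sequence of op names or ``(name, param)`` pairs drawn from
    hflip, vflip, rot+45, rot-45, brightness(delta in [-0.4, 0.4]) and
    zoom(z in [0.5, 1.5]).  Returns ``(image', boxes', trace)`` where the
    trace records each applied op with its resolved parameter.
    """
    rng = rng or np.random.default_rng()
    img = np.asarray(image)
    trace = []
    for op in ops:
        name, param = op if isinstance(op, tuple) else (op, None)
        if name not in ALLOWED_OPS:
            raise ValueError(f"unknown augmentation op {name!r}")
        if name == "hflip":
            img = img[:, ::-1].copy()
            boxes = [BoundingBox(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h)
                     for b in boxes]
        elif name == "vflip":
            img = img[::-1].copy()
            boxes = [BoundingBox(b.class_id, b.cx, 1.0 - b.cy, b.w, b.h)
                     for b in boxes]
        elif name in ("rot+45", "rot-45"):
            angle = 45.0 if name == "rot+45" else -45.0
            pil = Image.fromarray(img).rotate(angle, resample=Image.BILINEAR,
                                              fillcolor=0)
            img = np.asarray(pil)
            boxes = _rotate_boxes(boxes, angle)
        elif name == "brightness":
            delta = float(param) if param is not None else float(
                rng.uniform(-0.4, 0.4))
            if not -0.4 - 1e-9 <= delta <= 0.4 + 1e-9:
                raise ValueError(f"brightness delta {delta} outside [-0.4, 0.4]")
            img = np.clip(img.astype(np.float64) * (1.0 + delta), 0, 255
                          ).astype(np.uint8)
            param = delta
        elif name == "zoom":
            z = float(param) if param is not None else float(rng.uniform(0.5, 1.5))
            if not 0.5 - 1e-9 <= z <= 1.5 + 1e-9:
                raise ValueError(f"zoom factor {z} outside [0.5, 1.5]")
            img = _zoom_image(img, z)
            newb = []
            for b in boxes:
                nb = BoundingBox(b.class_id, 0.5 + (b.cx - 0.5) * z,
                                 0.5 + (b.cy - 0.5) * z, b.w * z, b.h * z)
                enclosed_area = nb.area()
                nb = nb.clipped()
                if enclosed_area > 0 and nb.area() / enclosed_area >= _MIN_AREA_SURVIVAL:
                    newb.append(nb)
            boxes = newb
            param = z
        trace.append((name, param))
    return img, boxes, trace


def _zoom_image(img: np.ndarray, z: float) -> np.ndarray:
    h, w = img.shape[:2]
    nh, nw = max(1, round(h * z)), max(1, round(w * z))
    pil = Image.fromarray(img).resize((nw, nh), Image.BILINEAR)
    arr = np.asarray(pil)
    out = np.zeros_like(img)
    if z >= 1.0:        # crop center
        y0, x0 = (nh - h) // 2, (nw - w) // 2
        out[:] = arr[y0:y0 + h, x0:x0 + w]
    else:               # paste into center
        y0, x0 = (h - nh) // 2, (w - nw) // 2
        out[y0:y0 + nh, x0:x0 + nw] = arr
    return out


def random_augment_ops(rng: np.random.Generator, n_ops: int | None = None):
    """Draw a random op combination from the allowed augmentation family."""
    pool = ["hflip", "vflip", "rot+45", "rot-45",
            ("brightness", float(rng.uniform(-0.4, 0.4))),
            ("zoom", float(rng.uniform(0.5, 1.5)))]
    n = int(n_ops) if n_ops is not None else int(rng.integers(1, 3))
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def expand_training_set(records, images: dict, multiplier: int = 3,
                        seed: int = 0):
    """Offline augmentation: training set of size n -> n * multiplier records.

    Only records with split == 'train' are expanded; each copy is provenance-
    linked to its origin.  Returns (all_records, images) with augmented images
    added to the store.
    """
    rng = np.random.default_rng(seed)
    out = list(records)
    images = dict(images)
    for rec in records:
        if rec.split != "train":
            continue
        for j in range(multiplier - 1):
            ops = random_augment_ops(rng)
            img, boxes, trace = augment_record(images[rec.image_id], rec.boxes,
                                               ops, rng)
            new_id = f"{rec.image_id}_aug{j}"
            out.append(LabeledImage(
                image_id=new_id, width=rec.width, height=rec.height,
                boxes=boxes, split="train",
                provenance=Provenance(origin_id=rec.image_id,
                                      ops=[list(t) for t in trace])))
            images[new_id] = img
    return out, images


# ---------------------------------------------------------------------------
# Leakage audit
# ---------------------------------------------------------------------------

def infer_provenance(image_id: str) -> Provenance:
    """Reconstruct provenance from the offline-augmentation naming scheme.

    Augmented records are written as ``<origin>_aug<N>``; anything else is
    treated as an original.  Used when auditing datasets read back from disk,
    where in-memory provenance is unavailable.
    """
    if "_aug" in image_id:
        origin = image_id.rsplit("_aug", 1)[0]
        return Provenance(origin_id=origin, ops=[["unknown", None]])
    return Provenance(origin_id=image_id)


def audit_leakage(manifest: SplitManifest, records) -> list[dict]:
    """Return violations; empty list means the pipeline is leakage-free.

    Violations: (a) an augmented record assigned to val/test; (b) a training
    record whose origin image belongs to val/test.
    """
    holdout = {i for i, s in manifest.assignment.items() if s in ("val", "test")}
    violations = []
    for rec in records:
        prov = rec.provenance
        augmented = prov is not None and not prov.is_original
        split = rec.split or manifest.assignment.get(rec.image_id)
        if augmented and split in ("val", "test"):
            violations.append({"kind": "augmented_in_holdout",
                               "record": rec.image_id,
                               "origin": prov.origin_id, "split": split})
        if split == "train" and prov is not None and prov.origin_id in holdout:
            violations.append({"kind": "holdout_derivative_in_train",
                               "record": rec.image_id,
                               "origin": prov.origin_id,
                               "origin_split": manifest.assignment[prov.origin_id]})
    return violations


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------

def balance_classes(records, target_per_class: int = 168,
                    exceptions: dict | None = None, seed: int = 0) -> dict:
    """Deterministic subsample plan standardizing image counts per class.

    Grouping key is each image's first-box class.  Classes below target are
    kept whole and reported as shortfalls instead of failing.  Returns
    {'keep': [ids], 'per_class': {class: n_kept}, 'shortfall': {class: n}}.
    """
    exceptions = exceptions or {}
    rng = np.random.default_rng(seed)
    groups: dict[int, list] = {}
    for rec in records:
        groups.setdefault(rec.first_class, []).append(rec.image_id)
    keep, per_class, shortfall = [], {}, {}
    for cls in sorted(groups):
        members = sorted(groups[cls])
        tgt = int(exceptions.get(cls, target_per_class))
        if len(members) <= tgt:
            chosen = members
            if len(members) < tgt:
                shortfall[cls] = tgt - len(members)
        else:
            chosen = sorted(rng.choice(members, size=tgt, replace=False).tolist())
        keep.extend(chosen)
        per_class[cls] = len(chosen)
    return {"keep": sorted(keep), "per_class": per_class, "shortfall": shortfall}


# ---------------------------------------------------------------------------
# Dataset descriptor
# ---------------------------------------------------------------------------

def write_dataset_descriptor(path, names: list[str], root: str = "."):
    import yaml
    desc = {"path": str(root), "train": "images", "val": "images",
            "names": {i: n for i, n in enumerate(names)}}
    Path(path).write_text(yaml.safe_dump(desc, sort_keys=False))


def read_dataset_descriptor(path) -> dict:
    import yaml
    return yaml.safe_load(Path(path).read_text())
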
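"""Training and inference for the detector.

Anchor-free dense prediction in the modern single-stage style: every feature
cell predicts class logits and four discretized edge-distance distributions
(distribution focal loss with ``reg_max`` bins).  Ground truths are assigned
by a task-aligned assigner (alignment score ``cls^alpha * IoU^beta`` over
cells whose centers fall inside the box, top-k per ground truth, conflicts
to the higher-IoU box).  Losses: CIoU box loss, two-bin distribution-focal
cross-entropy, and binary cross-entropy over classes, with gains 7.5/0.5/1.5.

The optimizer is Adamax with a constant learning rate (lr0 = lrf = 5e-3),
beta1 = 0.937, weight decay 5e-4, batch size 16 — the published training
configuration — with an optional linear warmup.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import autodiff as ad
from .autodiff import Tensor, softmax, log_softmax, bce_with_logits
from .arch import ArchSpec
from .model import DetectorNet, make_anchors
from .data import LabeledImage, SplitManifest, audit_leakage, LeakageError, \
    augment_record, random_augment_ops
from .metrics import Detection, evaluate, iou_matrix


@dataclass
class TrainConfig:
    optimizer: str = "adamax"
    lr0: float = 5e-3
    lrf: float = 5e-3               # equal to lr0 -> constant schedule
    momentum: float = 0.937         # Adamax beta1
    weight_decay: float = 5e-4
    batch_size: int = 16
    epochs: int = 200
    image_size: int = 640
    iou_tp_threshold: float = 0.5
    seed: int = 0
    mosaic: bool = False            # mosaic augmentation deliberately off
    box_gain: float = 7.5
    cls_gain: float = 0.5
    dfl_gain: float = 1.5
    assign_topk: int = 10
    assign_alpha: float = 0.5
    assign_beta: float = 6.0
    conf_eval: float = 0.001
    nms_iou: float = 0.7
    max_det: int = 300
    warmup_epochs: int = 1
    patience: int | None = None     # optional early stop, off by default
    augment: bool = True            # on-the-fly train-split augmentation

    def __post_init__(self):
        if self.lr0 <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")
        if self.mosaic:
            raise ValueError("mosaic augmentation is disabled by design")


@dataclass
class LossBreakdown:
    box_loss: float
    cls_loss: float
    dfl_loss: float
    total: float
    no_positives: bool = False


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def flatten_heads(head_maps: list[Tensor], reg_max: int, num_classes: int):
    """Concatenate per-head maps to (N, A, 4*reg_max) and (N, A, nc)."""
    dists, clss, shapes = [], [], []
    for t in head_maps:
        n, c, h, w = t.shape
        shapes.append((h, w))
        flat = t.reshape(n, c, h * w).transpose(0, 2, 1)
        dists.append(flat[:, :, : 4 * reg_max])
        clss.append(flat[:, :, 4 * reg_max:])
    return ad.concat(dists, axis=1), ad.concat(clss, axis=1), shapes


def decode_distances(pred_dist: Tensor, reg_max: int) -> Tensor:
    """Distribution logits (N, A, 4*reg_max) -> expected distances (N, A, 4)."""
    n, a, _ = pred_dist.shape
    d = softmax(pred_dist.reshape(n, a, 4, reg_max), axis=-1)
    proj = np.arange(reg_max, dtype=pred_dist.dtype).reshape(reg_max, 1)
    return d.matmul(proj).reshape(n, a, 4)


def distances_to_boxes(dist: Tensor | np.ndarray, points: np.ndarray,
                       strides: np.ndarray):
    """(l, t, r, b) cell distances at anchor points -> xyxy pixel boxes."""
    px, py = points[:, 0], points[:, 1]
    if isinstance(dist, Tensor):
        x1 = (Tensor(px) - dist[:, :, 0]) * strides
        y1 = (Tensor(py) - dist[:, :, 1]) * strides
        x2 = (Tensor(px) + dist[:, :, 2]) * strides
        y2 = (Tensor(py) + dist[:, :, 3]) * strides
        return ad.stack([x1, y1, x2, y2], axis=-1)
    d = np.asarray(dist)
    return np.stack([(px - d[..., 0]) * strides, (py - d[..., 1]) * strides,
                     (px + d[..., 2]) * strides, (py + d[..., 3]) * strides],
                    axis=-1)


# ---------------------------------------------------------------------------
# Task-aligned assignment
# ---------------------------------------------------------------------------

def assign_targets(pred_scores: np.ndarray, pred_boxes: np.ndarray,
                   anchor_points_px: np.ndarray, gt_boxes: np.ndarray,
                   gt_classes: np.ndarray, topk: int = 10, alpha: float = 0.5,
                   beta: float = 6.0):
    """Task-aligned assignment for one image (all inputs detached numpy).

    Returns (fg_mask (A,), target_gt (A,), target_scores (A, nc)).  With no
    ground truths every cell is background.  Each cell serves at most one
    ground truth; contested cells go to the higher-IoU box.
    """
    A, nc = pred_scores.shape
    fg = np.zeros(A, dtype=bool)
    tgt_idx = np.full(A, -1)
    tgt_scores = np.zeros((A, nc))
    G = len(gt_boxes)
    if G == 0:
        return fg, tgt_idx, tgt_scores

    ious = iou_matrix(gt_boxes, pred_boxes)                      # G, A
    inside = ((anchor_points_px[None, :, 0] > gt_boxes[:, None, 0])
              & (anchor_points_px[None, :, 0] < gt_boxes[:, None, 2])
              & (anchor_points_px[None, :, 1] > gt_boxes[:, None, 1])
              & (anchor_points_px[None, :, 1] < gt_boxes[:, None, 3]))
    cls_score = pred_scores[:, gt_classes].T                     # G, A
    align = (np.clip(cls_score, 1e-9, None) ** alpha) * (ious ** beta)
    align = np.where(inside, align, 0.0)

    candidate = np.zeros_like(align, dtype=bool)
    for g in range(G):
        avail = np.flatnonzero(align[g] > 0)
        if avail.size == 0:
            continue
        k = min(topk, avail.size)
        top = avail[np.argsort(-align[g, avail], kind="stable")[:k]]
        candidate[g, top] = True

    # resolve cells claimed by several ground truths: higher IoU wins
    claimed = candidate.sum(axis=0)
    multi = np.flatnonzero(claimed > 1)
    for a in multi:
        gs = np.flatnonzero(candidate[:, a])
        keep = gs[np.argmax(ious[gs, a])]
        candidate[:, a] = False
        candidate[keep, a] = True

    for g in range(G):
        cells = np.flatnonzero(candidate[g])
        if cells.size == 0:
            continue
        fg[cells] = True
        tgt_idx[cells] = g
        # normalized alignment: peak equals the ground truth's best IoU
        a_max = align[g, cells].max()
        i_max = ious[g, cells].max()
        norm = align[g, cells] * (i_max / (a_max + 1e-9))
        tgt_scores[cells, gt_classes[g]] = norm
    return fg, tgt_idx, tgt_scores


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _ciou(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Complete IoU between predicted boxes (M, 4 xyxy) and constants."""
    t = np.asarray(target)
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx1, ty1, tx2, ty2 = t[:, 0], t[:, 1], t[:, 2], t[:, 3]
    pw, ph = (px2 - px1).clamp(lo=eps), (py2 - py1).clamp(lo=eps)
    tw, th = tx2 - tx1, ty2 - ty1
    iw = (px2.minimum(tx2) - px1.maximum(tx1)).clamp(lo=0.0)
    ih = (py2.minimum(ty2) - py1.maximum(ty1)).clamp(lo=0.0)
    inter = iw * ih
    union = pw * ph + tw * th - inter + eps
    iou_t = inter / union
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((px1 + px2 - tx1 - tx2) ** 2 + (py1 + py2 - ty1 - ty2) ** 2) * 0.25
    v = (4.0 / np.pi ** 2) * ((Tensor(np.arctan(tw / th)) - (pw / ph).arctan()) ** 2)
    alpha = v.data / (1.0 - iou_t.data + v.data + eps)     # detached weight
    return iou_t - rho2 / c2 - v * alpha


def compute_losses(pred_dist: Tensor, pred_cls: Tensor, decoded_boxes: Tensor,
                   assignments, points: np.ndarray, strides: np.ndarray,
                   gt_list, reg_max: int, cfg: TrainConfig) -> tuple[Tensor, LossBreakdown]:
    """Combine CIoU, DFL and BCE losses over a batch.

    ``assignments`` is the per-image output of :func:`assign_targets`;
    ``gt_list`` the per-image (boxes_px, classes).  Returns the scalar total
    (a graph Tensor) and the detached breakdown.
    """
    N, A, nc = pred_cls.shape
    tgt_scores = np.zeros((N, A, nc), dtype=pred_cls.dtype)
    fg_n, fg_a, tbox, tscore = [], [], [], []
    for i, (fg, tgt_idx, scores) in enumerate(assignments):
        tgt_scores[i] = scores
        cells = np.flatnonzero(fg)
        boxes_px, _ = gt_list[i]
        for a in cells:
            fg_n.append(i)
            fg_a.append(a)
            tbox.append(boxes_px[tgt_idx[a]])
            tscore.append(scores[a].sum())
    score_sum = max(float(tgt_scores.sum()), 1.0)

    cls_loss = bce_with_logits(pred_cls, tgt_scores).sum() / score_sum

    if not fg_n:
        zero = Tensor(np.zeros((), dtype=pred_cls.dtype))
        total = cls_loss * cfg.cls_gain
        bd = LossBreakdown(0.0, float(cls_loss.data), 0.0,
                           float(total.data), no_positives=True)
        return total, bd

    fg_n = np.array(fg_n)
    fg_a = np.array(fg_a)
    tbox = np.array(tbox, dtype=pred_cls.dtype)               # M, 4 px
    w = np.array(tscore, dtype=pred_cls.dtype)
    w_sum = max(float(w.sum()), 1e-9)

    pbox = decoded_boxes[fg_n, fg_a]                           # M, 4 px
    ciou = _ciou(pbox, tbox)
    box_loss = ((1.0 - ciou) * w).sum() / w_sum

    # distribution focal loss on the two bins flanking each edge distance
    s = strides[fg_a]
    px, py = points[fg_a, 0], points[fg_a, 1]
    tdist = np.stack([px - tbox[:, 0] / s, py - tbox[:, 1] / s,
                      tbox[:, 2] / s - px, tbox[:, 3] / s - py], axis=-1)
    tdist = np.clip(tdist, 0.0, reg_max - 1 - 0.01)
    lo = np.floor(tdist)
    hi = lo + 1
    wl = hi - tdist
    wr = tdist - lo
    onehot = np.zeros((len(fg_n), 4, reg_max), dtype=pred_cls.dtype)
    rows = np.arange(len(fg_n))[:, None]
    edges = np.arange(4)[None, :]
    onehot[rows, edges, lo.astype(int)] += wl
    onehot[rows, edges, np.minimum(hi, reg_max - 1).astype(int)] += wr
    logp = log_softmax(pred_dist.reshape(N, A, 4, reg_max)[fg_n, fg_a], axis=-1)
    dfl_per = -(logp * onehot).sum(axis=(1, 2)) * 0.25        # mean over 4 edges
    dfl_loss = (dfl_per * w).sum() / w_sum

    total = (box_loss * cfg.box_gain + cls_loss * cfg.cls_gain
             + dfl_loss * cfg.dfl_gain)
    bd = LossBreakdown(float(box_loss.data), float(cls_loss.data),
                       float(dfl_loss.data), float(total.data))
    return total, bd


def batch_loss(model: DetectorNet, images: np.ndarray, gts,
               cfg: TrainConfig) -> tuple[Tensor, LossBreakdown]:
    """Forward + assignment + loss for one batch.

    ``gts``: per image list of (class_id, xyxy box in pixels).
    """
    spec = model.spec
    heads = model(images)
    pred_dist, pred_cls, shapes = flatten_heads(heads, spec.reg_max,
                                                spec.num_classes)
    points, strides = make_anchors(shapes, model.head_strides)
    dist = decode_distances(pred_dist, spec.reg_max)
    boxes_t = distances_to_boxes(dist, points, strides)        # graph, px

    pts_px = points * strides[:, None]
    scores_np = 1.0 / (1.0 + np.exp(-pred_cls.data))
    assignments, gt_list = [], []
    for i in range(images.shape[0]):
        g = gts[i]
        gb = np.array([b for _, b in g], float).reshape(-1, 4)
        gc = np.array([c for c, _ in g], int)
        assignments.append(assign_targets(
            scores_np[i], boxes_t.data[i], pts_px, gb, gc,
            cfg.assign_topk, cfg.assign_alpha, cfg.assign_beta))
        gt_list.append((gb, gc))
    return compute_losses(pred_dist, pred_cls, boxes_t, assignments,
                          points, strides, gt_list, spec.reg_max, cfg)


# ---------------------------------------------------------------------------
# NMS and prediction
# ---------------------------------------------------------------------------

def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    alive = np.ones(len(boxes), bool)
    for i in order:
        if not alive[i]:
            continue
        keep.append(int(i))
        alive[i] = False
        rest = np.flatnonzero(alive)
        if rest.size:
            ious = iou_matrix(boxes[i][None], boxes[rest])[0]
            alive[rest[ious > iou_thr]] = False
    return keep


def predict(model: DetectorNet, images: np.ndarray, conf_threshold: float = 0.25,
            nms_iou: float = 0.7, max_det: int = 300) -> list[list[Detection]]:
    """Decode + per-class greedy NMS; detections sorted by confidence."""
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValueError("conf_threshold must lie in [0, 1]")
    was_training = model.training
    model.eval()
    spec = model.spec
    heads = model(images)
    pred_dist, pred_cls, shapes = flatten_heads(heads, spec.reg_max,
                                                spec.num_classes)
    points, strides = make_anchors(shapes, model.head_strides)
    dist = decode_distances(pred_dist, spec.reg_max)
    boxes = distances_to_boxes(dist.data, points, strides)
    scores = 1.0 / (1.0 + np.exp(-pred_cls.data))
    H, W = images.shape[2], images.shape[3]
    out = []
    for i in range(images.shape[0]):
        dets: list[Detection] = []
        for c in range(spec.num_classes):
            sc = scores[i, :, c]
            sel = np.flatnonzero(sc >= conf_threshold)
            if sel.size == 0:
                continue
            bx = boxes[i, sel]
            bx = np.stack([np.clip(bx[:, 0], 0, W), np.clip(bx[:, 1], 0, H),
                           np.clip(bx[:, 2], 0, W), np.clip(bx[:, 3], 0, H)],
                          axis=-1)
            for k in nms(bx, sc[sel], nms_iou):
                dets.append(Detection(box=bx[k], class_id=c,
                                      conf=float(sc[sel][k])))
        dets.sort(key=lambda d: -d.conf)
        out.append(dets[:max_det])
    if was_training:
        model.train()
    return out


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _load_image(rec: LabeledImage, images: dict | None) -> np.ndarray:
    if images is not None and rec.image_id in images:
        return images[rec.image_id]
    with Image.open(rec.path) as im:
        return np.asarray(im.convert("RGB"))


def _to_batch(imgs: list[np.ndarray], size: int) -> np.ndarray:
    batch = np.zeros((len(imgs), 3, size, size), dtype=np.float32)
    for i, im in enumerate(imgs):
        if im.shape[0] != size or im.shape[1] != size:
            im = np.asarray(Image.fromarray(im).resize((size, size),
                                                       Image.BILINEAR))
        batch[i] = im.astype(np.float32).transpose(2, 0, 1) / 255.0
    return batch


def _gts_px(rec: LabeledImage, size: int):
    return [(b.class_id, b.to_xyxy(size, size)) for b in rec.boxes]


@dataclass
class Checkpoint:
    spec: ArchSpec
    weights: list                   # numpy arrays, parameter order
    buffers: list = field(default_factory=list)   # batch-norm running stats
    config: TrainConfig | None = None
    best_map50: float = float("nan")

    @classmethod
    def of(cls, model: DetectorNet, config=None, best_map50=float("nan")):
        return cls(spec=model.spec,
                   weights=[p.data.copy() for p in model.parameters()],
                   buffers=[b.copy() for b in model.buffers()],
                   config=config, best_map50=best_map50)

    def save(self, path):
        path = Path(path)
        meta = {"spec": self.spec.to_dict(),
                "config": asdict(self.config) if self.config else None,
                "best_map50": self.best_map50,
                "n_weights": len(self.weights), "n_buffers": len(self.buffers)}
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.buffers)})
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        weights = [z[f"w{i}"] for i in range(meta["n_weights"])]
        buffers = [z[f"b{i}"] for i in range(meta["n_buffers"])]
        cfg = TrainConfig(**meta["config"]) if meta["config"] else None
        return cls(spec=ArchSpec.from_dict(meta["spec"]), weights=weights,
                   buffers=buffers, config=cfg, best_map50=meta["best_map50"])

    def build_model(self, seed: int = 0) -> DetectorNet:
        model = DetectorNet(self.spec, seed=seed)
        for p, w in zip(model.parameters(), self.weights):
            p.data = w.astype(p.data.dtype).copy()
        if self.buffers:
            model.load_buffers(self.buffers)
        return model


def evaluate_model(model: DetectorNet, records, images: dict | None,
                   cfg: TrainConfig, class_names: list):
    preds, gts = {}, {}
    size = cfg.image_size
    for start in range(0, len(records), cfg.batch_size):
        chunk = records[start:start + cfg.batch_size]
        batch = _to_batch([_load_image(r, images) for r in chunk], size)
        dets = predict(model, batch, cfg.conf_eval, cfg.nms_iou, cfg.max_det)
        for r, d in zip(chunk, dets):
            preds[r.image_id] = d
            gts[r.image_id] = _gts_px(r, size)
    return evaluate(preds, gts, class_names, iou_threshold=cfg.iou_tp_threshold)


def train(model: DetectorNet, train_records, val_records, cfg: TrainConfig,
          images: dict | None = None, class_names: list | None = None,
          manifest: SplitManifest | None = None, log=None):
    """Train the detector; returns (best Checkpoint, history list).

    ``images`` optionally maps image_id -> uint8 array (otherwise records are
    loaded from their paths).  If a manifest is supplied, a leakage audit
    runs before epoch 0 and any violation aborts training.
    """
    if manifest is not None:
        violations = audit_leakage(manifest, list(train_records) + list(val_records))
        if violations:
            raise LeakageError(f"{len(violations)} leakage violations; "
                               f"first: {violations[0]}")
    class_names = class_names or [str(i) for i in range(model.spec.num_classes)]
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    opt = ad.Adamax(params, lr=cfg.lr0, betas=(cfg.momentum, 0.999),
                    weight_decay=cfg.weight_decay)
    history = []
    best = Checkpoint.of(model, config=cfg, best_map50=float("-inf"))
    size = cfg.image_size
    n_batches = max(1, int(np.ceil(len(train_records) / cfg.batch_size)))
    warmup_steps = cfg.warmup_epochs * n_batches
    step = 0
    bad_epochs = 0
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_records))
        ep_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs, gts = [], []
            for i in idx:
                rec = train_records[i]
                img = _load_image(rec, images)
                boxes = rec.boxes
                if cfg.augment and rec.split in (None, "train"):
                    img, boxes, _ = augment_record(img, boxes,
                                                   random_augment_ops(rng), rng)
                imgs.append(img)
                gts.append([(b.class_id, b.to_xyxy(size, size)) for b in boxes])
            batch = _to_batch(imgs, size)
            if step < warmup_steps:
                opt.lr = cfg.lr0 * (0.1 + 0.9 * step / warmup_steps)
            else:
                opt.lr = cfg.lr0
            total, bd = batch_loss(model, batch, gts, cfg)
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_losses.append(bd)
            step += 1
        mean = lambda k: float(np.mean([getattr(b, k) for b in ep_losses]))
        entry = {"epoch": epoch, "box_loss": mean("box_loss"),
                 "cls_loss": mean("cls_loss"), "dfl_loss": mean("dfl_loss"),
                 "total": mean("total")}
        if val_records:
            report = evaluate_model(model, val_records, images, cfg, class_names)
            t = report.totals
            entry.update({"val_precision": t["precision"],
                          "val_recall": t["recall"],
                          "val_map50": t["map50"], "val_dsc": t["dsc"]})
            score = t["map50"] if not np.isnan(t["map50"]) else 0.0
            if score > best.best_map50:
                best = Checkpoint.of(model, config=cfg, best_map50=score)
                bad_epochs = 0
            else:
                bad_epochs += 1
        history.append(entry)
        if log:
            log(entry)
        if cfg.patience is not None and bad_epochs > cfg.patience:
            break
    if best.best_map50 == float("-inf"):
        best = Checkpoint.of(model, config=cfg)
    return best, history


def write_history_csv(history: list[dict], path):
    if not history:
        Path(path).write_text("")
        return
    keys = sorted({k for h in history for k in h}, key=lambda k: (k != "epoch", k))
    with open(path, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=keys)
        wr.writeheader()
        for h in history:
            wr.writerow(h)
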
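"""Detection evaluation: IoU matching, precision/recall/DSC, AP50, confusion.

The evaluation follows the standard single-IoU protocol: a detection is a
true positive when it is the highest-confidence unmatched prediction with
IoU >= 0.5 against a ground-truth box of its class (greedy one-to-one
matching).  Precision = TP/(TP+FP), recall = TP/(TP+FN) and the Dice
similarity coefficient DSC = 2TP/(2TP+FP+FN) — the harmonic mean of
precision and recall.  Average precision interpolates the monotone precision
envelope at 101 recall points; mAP50 averages per-class AP over the included
classes.  A (C+1) x (C+1) confusion matrix with a background row/column
captures cross-class confusions and missed/spurious detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNDEFINED = float("nan")


@dataclass
class Detection:
    box: np.ndarray            # xyxy, pixels
    class_id: int
    conf: float


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0                # undefined for detection; reported as 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class MetricReport:
    class_names: list
    per_class: dict            # class_id -> {precision, recall, ap50, dsc, n_gt, n_pred}
    totals: dict
    detected_class_list: list
    confusion: np.ndarray | None = None
    operating_conf: float = 0.0


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def iou(box_a, box_b) -> float:
    """Intersection-over-union of two xyxy boxes (0 for degenerate boxes)."""
    a, b = np.asarray(box_a, float), np.asarray(box_b, float)
    area_a = max(0.0, a[2] - a[0]) * max(0.0, a[3] - a[1])
    area_b = max(0.0, b[2] - b[0]) * max(0.0, b[3] - b[1])
    if area_a == 0.0 or area_b == 0.0:
        import warnings
        warnings.warn("degenerate zero-area box in IoU", stacklevel=2)
        return 0.0
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU, (len(a), len(b)); accepts empty inputs."""
    a = np.asarray(boxes_a, float).reshape(-1, 4)
    b = np.asarray(boxes_b, float).reshape(-1, 4)
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.prod(np.clip(a[:, 2:] - a[:, :2], 0, None), axis=1)
    area_b = np.prod(np.clip(b[:, 2:] - b[:, :2], 0, None), axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_detections(detections: list[Detection], ground_truths,
                     iou_threshold: float = 0.5):
    """Greedy one-to-one matching within one image and one class pool.

    Detections must be sorted by descending confidence; each takes the
    highest-IoU unmatched ground truth of its class with IoU >= threshold
    (ties: higher IoU, then earlier detection).  Returns (EvalCounts,
    match pairs [(det_idx, gt_idx, iou)], per-detection TP flags).
    """
    confs = [d.conf for d in detections]
    if any(confs[i] < confs[i + 1] for i in range(len(confs) - 1)):
        detections = sorted(detections, key=lambda d: -d.conf)
    gt_boxes = [np.asarray(g[1], float) for g in ground_truths]
    gt_cls = [int(g[0]) for g in ground_truths]
    matched_gt = set()
    pairs, tp_flags = [], []
    for di, det in enumerate(detections):
        best_iou, best_gi = 0.0, -1
        for gi, (gcls, gbox) in enumerate(zip(gt_cls, gt_boxes)):
            if gi in matched_gt or gcls != det.class_id:
                continue
            v = iou(det.box, gbox)
            if v >= iou_threshold and v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi >= 0:
            matched_gt.add(best_gi)
            pairs.append((di, best_gi, best_iou))
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    tp = sum(tp_flags)
    counts = EvalCounts(tp=tp, fp=len(detections) - tp,
                        fn=len(ground_truths) - tp)
    return counts, pairs, tp_flags


def precision_recall_dsc(counts: EvalCounts):
    """(P, R, DSC) from counts; undefined ratios are NaN, distinct from 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else UNDEFINED
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else UNDEFINED
    denom = 2 * counts.tp + counts.fp + counts.fn
    d = 2 * counts.tp / denom if denom else UNDEFINED
    return p, r, d


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------

def average_precision(confidences, tp_flags, n_gt: int,
                      interpolation: str = "101point") -> float:
    """AP at a single IoU threshold from per-detection (conf, is_TP) records.

    Ties in confidence are resolved by keeping the supplied order after a
    stable sort, so equal-confidence permutations are reproducible.
    ``interpolation``: '101point' (default) or 'continuous' (all-point).
    """
    if n_gt == 0:
        return UNDEFINED
    conf = np.asarray(confidences, float)
    flags = np.asarray(tp_flags, bool)
    if conf.size == 0:
        return 0.0
    order = np.argsort(-conf, kind="stable")
    flags = flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone precision envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "101point":
        pts = np.linspace(0, 1, 101)
        idx = np.searchsorted(recall, pts, side="left")
        sampled = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
        return float(sampled.mean())
    # all-point: integrate the envelope over recall
    r = np.concatenate([[0.0], recall])
    e = np.concatenate([[env[0]], env])
    return float(np.sum((r[1:] - r[:-1]) * e[1:]))


# ---------------------------------------------------------------------------
# Full evaluation
# ---------------------------------------------------------------------------

def _collect(predictions: dict, ground_truths: dict, num_classes: int,
             iou_threshold: float):
    """Pool per-class (conf, tp) records and counts over all images."""
    if set(predictions) != set(ground_truths):
        missing = set(predictions) ^ set(ground_truths)
        raise ValueError(f"image id mismatch between predictions and ground "
                         f"truths: {sorted(missing)[:10]}")
    records = {c: [] for c in range(num_classes)}        # (conf, tp)
    n_gt = {c: 0 for c in range(num_classes)}
    for img_id in ground_truths:
        gts = ground_truths[img_id]
        dets = sorted(predictions[img_id], key=lambda d: -d.conf)
        for c in range(num_classes):
            c_dets = [d for d in dets if d.class_id == c]
            c_gts = [g for g in gts if int(g[0]) == c]
            n_gt[c] += len(c_gts)
            _, _, flags = match_detections(c_dets, c_gts, iou_threshold)
            for d, f in zip(c_dets, flags):
                records[c].append((d.conf, f))
    return records, n_gt


def evaluate(predictions: dict, ground_truths: dict, class_names: list,
             iou_threshold: float = 0.5, interpolation: str = "101point",
             count_undetected_as_zero: bool = False,
             confusion_conf: float = 0.25, confusion_iou: float = 0.45
             ) -> MetricReport:
    """Per-class and total P/R/AP50/DSC plus the background confusion matrix.

    ``predictions``: image id -> list[Detection]; ``ground_truths``: image id
    -> list[(class_id, xyxy box)].  P/R/DSC are reported at the confidence
    threshold maximizing pooled F1.  The "Total" row averages classes with at
    least one ground truth and one prediction (undetected classes are listed
    in ``detected_class_list``'s complement); pass
    ``count_undetected_as_zero`` to average their AP as 0 instead.
    """
    C = len(class_names)
    records, n_gt = _collect(predictions, ground_truths, C, iou_threshold)

    # global max-F1 operating point on the pooled PR curve
    pooled = sorted([rc for c in range(C) for rc in records[c]],
                    key=lambda t: -t[0])
    total_gt = sum(n_gt.values())
    best_conf = 0.0
    if pooled and total_gt:
        confs = np.array([t[0] for t in pooled])
        flags = np.array([t[1] for t in pooled], bool)
        tp_cum = np.cumsum(flags)
        fp_cum = np.cumsum(~flags)
        rec = tp_cum / total_gt
        prec = tp_cum / (tp_cum + fp_cum)
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
        best_conf = float(confs[int(np.argmax(f1))])

    per_class = {}
    detected = []
    for c in range(C):
        recs = records[c]
        n_pred = len(recs)
        if n_pred:
            detected.append(c)
        kept = [(cf, f) for cf, f in recs if cf >= best_conf]
        tp = sum(1 for _, f in kept if f)
        counts = EvalCounts(tp=tp, fp=len(kept) - tp, fn=n_gt[c] - tp)
        p, r, d = precision_recall_dsc(counts)
        ap = average_precision([cf for cf, _ in recs], [f for _, f in recs],
                               n_gt[c], interpolation)
        per_class[c] = {"precision": p, "recall": r, "ap50": ap, "dsc": d,
                        "n_gt": n_gt[c], "n_pred": n_pred}

    def _macro(key):
        if count_undetected_as_zero:
            vals = [0.0 if np.isnan(per_class[c][key]) or per_class[c]["n_pred"] == 0
                    else per_class[c][key]
                    for c in range(C) if per_class[c]["n_gt"] > 0]
        else:
            vals = [per_class[c][key] for c in range(C)
                    if per_class[c]["n_gt"] > 0 and per_class[c]["n_pred"] > 0
                    and not np.isnan(per_class[c][key])]
        return float(np.mean(vals)) if vals else UNDEFINED

    totals = {k: _macro(k) for k in ("precision", "recall", "ap50", "dsc")}
    totals["map50"] = totals.pop("ap50")
    conf_mat = confusion_matrix(predictions, ground_truths, C,
                                conf=confusion_conf, iou_thr=confusion_iou)
    return MetricReport(class_names=list(class_names), per_class=per_class,
                        totals=totals, detected_class_list=detected,
                        confusion=conf_mat, operating_conf=best_conf)


def confusion_matrix(predictions: dict, ground_truths: dict, num_classes: int,
                     conf: float = 0.25, iou_thr: float = 0.45) -> np.ndarray:
    """(C+1) x (C+1) detection confusion matrix.

    Rows are predicted class, columns true class; the extra index C is
    background: a ground truth with no matching prediction counts in
    (background, true); a prediction matching no ground truth counts in
    (predicted, background).  Matching is greedy on IoU across classes.
    """
    C = num_classes
    m = np.zeros((C + 1, C + 1), dtype=int)
    for img_id in ground_truths:
        gts = ground_truths[img_id]
        dets = sorted([d for d in predictions.get(img_id, [])
                       if d.conf >= conf], key=lambda d: -d.conf)
        gt_boxes = np.array([g[1] for g in gts], float).reshape(-1, 4)
        det_boxes = np.array([d.box for d in dets], float).reshape(-1, 4)
        ious = iou_matrix(det_boxes, gt_boxes)
        taken = set()
        matched_det = set()
        # greedy over descending IoU among pairs above threshold
        if ious.size:
            order = np.dstack(np.unravel_index(np.argsort(-ious, axis=None),
                                               ious.shape))[0]
            for di, gi in order:
                if ious[di, gi] < iou_thr:
                    break
                if di in matched_det or gi in taken:
                    continue
                matched_det.add(di)
                taken.add(gi)
                m[dets[di].class_id, int(gts[gi][0])] += 1
        for gi, g in enumerate(gts):
            if gi not in taken:
                m[C, int(g[0])] += 1
        for di, d in enumerate(dets):
            if di not in matched_det:
                m[d.class_id, C] += 1
    return m


def report_to_rows(report: MetricReport) -> list[dict]:
    """Tabular rows (per-class + Total) mirroring the published table shape."""
    rows = []
    for c, name in enumerate(report.class_names):
        pc = report.per_class[c]
        rows.append({"class": name, **{k: pc[k] for k in
                                       ("precision", "recall", "ap50", "dsc")},
                     "n_gt": pc["n_gt"], "n_pred": pc["n_pred"]})
    t = report.totals
    rows.append({"class": "Total", "precision": t["precision"],
                 "recall": t["recall"], "ap50": t["map50"], "dsc": t["dsc"],
                 "n_gt": sum(r["n_gt"] for r in rows),
                 "n_pred": sum(r["n_pred"] for r in rows)})
    return rows
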
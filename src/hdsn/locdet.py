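"""Saliency-map object localization, detection, and PR / fppi evaluation.

A trained network's class saliency map (rectified unit responses summed
across channels and scales, resampled to the input resolution) is turned
into detections by a uniform box filter followed by greedy non-maximum
suppression.  Evaluation follows the standard protocol: greedy
highest-score-first matching of detections to ground-truth boxes at an IoU
threshold, all-point-interpolated average precision, and detection rate at
a given number of false positives per image.

Boxes are 0-based, half-open (x, y, w, h) in pixels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "DetectionBox",
    "box_iou",
    "detect",
    "nms",
    "pr_curve",
    "detection_rate_at_fppi",
    "read_boxes_csv",
    "write_boxes_csv",
]


@dataclass(frozen=True)
class DetectionBox:
    x: int
    y: int
    w: int
    h: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box extent must be positive")
        if self.x < 0 or self.y < 0:
            raise ValueError("box origin must be non-negative")

    def as_tuple(self):
        return (self.x, self.y, self.w, self.h)


def box_iou(a, b):
    """Intersection-over-union of two (x, y, w, h) half-open boxes."""
    ax, ay, aw, ah = a[:4]
    bx, by, bw, bh = b[:4]
    ix = max(0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def nms(boxes, iou_threshold=0.5):
    """Greedy non-maximum suppression: keep highest-score boxes whose pairwise
    IoU with every already-kept box is <= the threshold.

    Ties in score are broken by input index (deterministic, order independent
    given distinct (score, index) keys after sorting by score descending then
    by a canonical geometric key)."""
    order = sorted(range(len(boxes)),
                   key=lambda i: (-boxes[i].score, boxes[i].x, boxes[i].y, boxes[i].w, boxes[i].h))
    kept = []
    for i in order:
        if all(box_iou(boxes[i].as_tuple(), boxes[j].as_tuple()) <= iou_threshold for j in kept):
            kept.append(i)
    return [boxes[i] for i in kept]


def detect(saliency_map, box_size, nms_iou=0.5, n_max=100, threshold=0.0):
    """Box-filter + NMS detection on a saliency map.

    Every position is scored by the mean saliency inside a ``box_size``
    square; local candidates above ``threshold`` are reduced by greedy NMS
    and the ``n_max`` highest survive, ordered by descending score.
    """
    saliency_map = np.asarray(saliency_map, dtype=float)
    if isinstance(box_size, int):
        bh = bw = box_size
    else:
        bw, bh = box_size
    H, W = saliency_map.shape
    if bh > H or bw > W:
        raise ValueError(f"box {bw}x{bh} larger than map {W}x{H}")
    scores = uniform_filter(saliency_map, size=(bh, bw), mode="constant", cval=0.0)
    # valid top-left positions: center offsets of the filter
    oy, ox = bh // 2, bw // 2
    valid = scores[oy:oy + H - bh + 1, ox:ox + W - bw + 1]
    ys, xs = np.nonzero(valid > threshold)
    order = np.argsort(-valid[ys, xs], kind="stable")
    # cap the candidate pool before the quadratic NMS pass
    order = order[: max(50 * n_max, 1000)]
    candidates = [DetectionBox(x=int(xs[i]), y=int(ys[i]), w=bw, h=bh, score=float(valid[ys[i], xs[i]]))
                  for i in order]
    return nms(candidates, nms_iou)[:n_max]


def _match_detections(detections, truth, match_iou):
    """Greedy descending-score matching; returns a TP/FP flag per detection.

    ``detections``: list of (image_id, DetectionBox); ``truth``: dict
    image_id -> list of ground-truth boxes.  Each truth box matches at most
    one detection.
    """
    order = sorted(range(len(detections)), key=lambda i: -detections[i][1].score)
    used = {img: np.zeros(len(b), dtype=bool) for img, b in truth.items()}
    tp = np.zeros(len(detections), dtype=bool)
    for i in order:
        img, box = detections[i]
        gt = truth.get(img, [])
        best_j, best_iou = -1, -1.0
        for j, g in enumerate(gt):
            if img in used and used[img][j]:
                continue
            iou = box_iou(box.as_tuple(), g.as_tuple() if hasattr(g, "as_tuple") else g)
            if iou >= match_iou and iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0:
            used[img][best_j] = True
            tp[i] = True
    return tp


def pr_curve(detections, truth, match_iou=0.5):
    """Precision/recall arrays and all-point-interpolated average precision.

    ``detections``: list of (image_id, DetectionBox); ``truth``: dict of
    image_id -> list of annotation boxes.  Duplicate hits on an already
    matched truth box count as false positives.
    """
    n_truth = sum(len(b) for b in truth.values())
    if n_truth == 0:
        raise ValueError("ground truth is empty: recall undefined")
    if not detections:
        return np.array([]), np.array([]), 0.0
    tp = _match_detections(detections, truth, match_iou)
    order = sorted(range(len(detections)), key=lambda i: -detections[i][1].score)
    tp_sorted = tp[order]
    cum_tp = np.cumsum(tp_sorted)
    cum_fp = np.cumsum(~tp_sorted)
    precision = cum_tp / (cum_tp + cum_fp)
    recall = cum_tp / n_truth
    # all-point interpolation: precision envelope, integrate over recall steps
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for p, r in zip(prec_env, recall):
        ap += p * (r - prev_r)
        prev_r = r
    return precision, recall, float(ap)


def detection_rate_at_fppi(detections, truth, fppi_level, match_iou=0.5, n_images=None):
    """Recall at the loosest score threshold with <= fppi_level false positives/image.

    Sweeps the score threshold over all detection scores (plus +inf) and
    reports the truth recall of the largest detection set whose false
    positives per image stay at or below the level.
    """
    n_truth = sum(len(b) for b in truth.values())
    if n_truth == 0:
        raise ValueError("ground truth is empty")
    n_images = n_images if n_images is not None else max(len(truth), 1)
    if not detections:
        return 0.0
    tp = _match_detections(detections, truth, match_iou)
    scores = np.array([d[1].score for d in detections])
    order = np.argsort(-scores)
    cum_tp = np.cumsum(tp[order])
    cum_fp = np.cumsum(~tp[order])
    best = 0.0
    for k in range(len(order)):
        if cum_fp[k] / n_images <= fppi_level:
            best = max(best, cum_tp[k] / n_truth)
    return float(best)


def write_boxes_csv(path, rows):
    """Write detections/ground truth as image,x,y,w,h[,score] CSV."""
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["image", "x", "y", "w", "h", "score"])
        for img, box in rows:
            writer.writerow([img, box.x, box.y, box.w, box.h, box.score])


def read_boxes_csv(path):
    """Read an image,x,y,w,h[,score] CSV into (image_id, DetectionBox) pairs."""
    out = []
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            out.append((row["image"], DetectionBox(x=int(row["x"]), y=int(row["y"]),
                                                   w=int(row["w"]), h=int(row["h"]),
                                                   score=float(row.get("score", 0) or 0))))
    return out
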
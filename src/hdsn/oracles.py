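"""Independent brute-force reference implementations.

Deliberately naive (loop-based, exhaustive) versions of operations the
package implements with vectorized or greedy algorithms, used to validate
those implementations on small inputs.  Nothing here shares code with the
production paths.
"""

from __future__ import annotations

import numpy as np

__all__ = ["conv_same_zero_pad", "nms_bruteforce", "fppi_sweep_bruteforce"]


def conv_same_zero_pad(image, kernel):
    """Direct O(N^2 k^2) correlation with 'same' output and zero padding."""
    H, W = image.shape
    kh, kw = kernel.shape
    oy, ox = kh // 2, kw // 2
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for u in range(kh):
                for v in range(kw):
                    y, x = i + u - oy, j + v - ox
                    if 0 <= y < H and 0 <= x < W:
                        acc += image[y, x] * kernel[u, v]
            out[i, j] = acc
    return out


def _iou(a, b):
    ix = max(0, min(a[0] + a[2], b[0] + b[2]) - max(a[0], b[0]))
    iy = max(0, min(a[1] + a[3], b[1] + b[3]) - max(a[1], b[1]))
    inter = ix * iy
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union else 0.0


def nms_bruteforce(boxes, iou_threshold):
    """Exhaustive suppression: enumerate boxes best-first, drop any that
    overlaps an already-selected box beyond the threshold.

    ``boxes`` are (x, y, w, h, score) tuples; returns selected tuples in
    descending-score order, ties broken by coordinates.
    """
    remaining = sorted(boxes, key=lambda b: (-b[4], b[0], b[1], b[2], b[3]))
    selected = []
    while remaining:
        best = remaining.pop(0)
        selected.append(best)
        remaining = [b for b in remaining if _iou(best, b) <= iou_threshold]
    return selected


def fppi_sweep_bruteforce(scored_matches, n_truth, n_images, fppi_level):
    """Exhaustive threshold sweep for detection rate at a fppi level.

    ``scored_matches`` is a list of (score, is_true_positive) pairs with the
    matching already decided.  Every candidate threshold (each score) is
    tried; returns the best recall among sets with <= fppi_level false
    positives per image.
    """
    best = 0.0
    thresholds = sorted({s for s, _ in scored_matches})
    for thr in thresholds:
        kept = [(s, tp) for s, tp in scored_matches if s >= thr]
        fp = sum(1 for _, tp in kept if not tp)
        if fp / n_images <= fppi_level:
            recall = sum(1 for _, tp in kept if tp) / n_truth
            best = max(best, recall)
    return best
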
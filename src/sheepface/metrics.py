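"""Verification and identification metrics.

Implements the metric suite used for model evaluation: one-vs-rest confusion
tallies, precision/recall/F1/accuracy, box IoU, mean average precision at
IoU 0.5, and two equal-error-rate variants: ``eer_eq11`` (a pooled
misclassification rate, (FP+FN)/total) and ``eer_roc`` (the ROC operating
point where the false-acceptance and false-rejection rates cross, linearly
interpolated between thresholds).  Zero denominators yield 0 with an explicit
flag rather than NaN.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class ConfusionCounts:
    """One-vs-rest tallies per class plus micro-pooled totals."""

    per_class: dict
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted, true) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("length mismatch")
    classes = sorted(set(predicted.tolist()) | set(true.tolist()))
    per_class = {}
    for c in classes:
        p, t = predicted == c, true == c
        per_class[c] = {
            "tp": int((p & t).sum()), "fp": int((p & ~t).sum()),
            "fn": int((~p & t).sum()), "tn": int((~p & ~t).sum()),
        }
    pooled = {k: sum(d[k] for d in per_class.values()) for k in ("tp", "fp", "tn", "fn")}
    return ConfusionCounts(per_class=per_class, **pooled)


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def classification_metrics(c: ConfusionCounts) -> dict:
    """Precision, recall, F1 and accuracy from pooled counts."""
    precision, f1_p = _safe_div(c.tp, c.tp + c.fp)
    recall, f1_r = _safe_div(c.tp, c.tp + c.fn)
    f1, f1_flag = _safe_div(2 * precision * recall, precision + recall)
    accuracy, acc_flag = _safe_div(c.tp + c.tn, c.total)
    return {
        "precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy,
        "degenerate": f1_p or f1_r or f1_flag or acc_flag,
    }


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    xa, ya, wa, ha = box_a
    xb, yb, wb, hb = box_b
    if wa < 0 or ha < 0 or wb < 0 or hb < 0:
        raise ValueError("boxes need nonnegative width/height")
    ix = max(0.0, min(xa + wa, xb + wb) - max(xa, xb))
    iy = max(0.0, min(ya + ha, yb + hb) - max(ya, yb))
    inter = ix * iy
    union = wa * ha + wb * hb - inter
    val, _ = _safe_div(inter, union)
    return val


def average_precision(matches: np.ndarray, n_gt: int) -> float:
    """All-point-interpolated AP given score-ranked TP/FP flags."""
    if n_gt == 0:
        return 0.0
    tp = np.cumsum(matches)
    fp = np.cumsum(~matches)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope, integrate over recall steps
    mrec = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def map_at_50(predictions, ground_truth, iou_threshold: float = 0.5) -> dict:
    """Mean AP over classes at IoU >= ``iou_threshold``.

    ``predictions``: iterable of (class, score, box); ``ground_truth``:
    iterable of (class, box).  A prediction is a true positive iff its class
    matches and it overlaps a not-yet-matched ground truth with sufficient
    IoU.  Classes with no ground truth are excluded and flagged.
    """
    preds_by_class: dict = {}
    for cls, score, box in predictions:
        preds_by_class.setdefault(cls, []).append((float(score), box))
    gts_by_class: dict = {}
    for cls, box in ground_truth:
        gts_by_class.setdefault(cls, []).append(box)

    aps, skipped = {}, []
    for cls in sorted(set(preds_by_class) | set(gts_by_class), key=str):
        gts = gts_by_class.get(cls, [])
        if not gts:
            skipped.append(cls)
            continue
        preds = sorted(preds_by_class.get(cls, []), key=lambda p: -p[0])
        matched = [False] * len(gts)
        flags = np.zeros(len(preds), dtype=bool)
        for i, (_, box) in enumerate(preds):
            best, best_j = 0.0, -1
            for j, gt_box in enumerate(gts):
                if matched[j]:
                    continue
                ov = iou(box, gt_box)
                if ov > best:
                    best, best_j = ov, j
            if best >= iou_threshold and best_j >= 0:
                matched[best_j] = True
                flags[i] = True
        aps[cls] = average_precision(flags, len(gts))
    mean_ap = float(np.mean(list(aps.values()))) if aps else 0.0
    return {"map": mean_ap, "per_class": aps, "classes_without_gt": skipped}


def eer_eq11(counts: ConfusionCounts) -> float:
    """Pooled misclassification rate ``(FP+FN)/(TP+TN+FP+FN)``."""
    val, _ = _safe_div(counts.fp + counts.fn, counts.total)
    return val


def roc_curves(scores, same) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FAR and FRR as functions of the acceptance threshold.

    Acceptance rule: pair accepted as "same" when score >= threshold.
    Returns (thresholds, FAR, FRR); thresholds include a sentinel above the
    maximum score so both endpoints of the trade-off are covered.
    """
    scores = np.asarray(scores, dtype=np.float64)
    same = np.asarray(same, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty score set")
    if not same.any() or same.all():
        raise ValueError("need both same-pairs and different-pairs")
    uniq = np.unique(scores)
    span = uniq[-1] - uniq[0]
    thresholds = np.concatenate([uniq, [uniq[-1] + max(span, 1.0) * 1e-3]])
    pos = np.sort(scores[same])
    neg = np.sort(scores[~same])
    far = (len(neg) - np.searchsorted(neg, thresholds, side="left")) / len(neg)
    frr = np.searchsorted(pos, thresholds, side="left") / len(pos)
    return thresholds, far, frr


def eer_roc(scores, same) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Equal error rate at the FAR = FRR crossing (linear interpolation)."""
    thresholds, far, frr = roc_curves(scores, same)
    d = far - frr  # monotone nonincreasing from >=0 to <=0
    k = int(np.where(d <= 0)[0][0]) if (d <= 0).any() else len(d) - 1
    if k == 0 or d[k] == 0:
        eer = float((far[k] + frr[k]) / 2.0)
    else:
        d0, d1 = d[k - 1], d[k]
        lam = d0 / (d0 - d1) if d0 != d1 else 0.5
        eer = float(far[k - 1] + lam * (far[k] - far[k - 1]))
        eer = (eer + float(frr[k - 1] + lam * (frr[k] - frr[k - 1]))) / 2.0
    return eer, thresholds, far, frr
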
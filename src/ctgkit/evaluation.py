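"""Detection evaluation: IoU, greedy matching, precision/recall/accuracy.

Scores any detector's boxes (the rule engine projected to boxes, or an
external object detector) against ground-truth boxes.  Areas use the
1-based inclusive pixel convention, ``(xmax−xmin+1)·(ymax−ymin+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charts import BoundingBox


@dataclass
class MatchResult:
    pairs: list                    # (prediction, truth, iou)
    unmatched_predictions: list
    unmatched_truths: list


@dataclass
class EvalReport:
    mean_iou: float
    precision: float
    recall: float
    feature_accuracy: float
    per_class: dict = field(default_factory=dict)
    n_true: int = 0
    n_pred: int = 0
    n_matched: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_iou": self.mean_iou, "precision": self.precision,
            "recall": self.recall, "feature_accuracy": self.feature_accuracy,
            "n_true": self.n_true, "n_pred": self.n_pred,
            "n_matched": self.n_matched, "per_class": self.per_class,
        }


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union with inclusive pixel areas; symmetric."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin) + 1
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin) + 1
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    area_a = (a.xmax - a.xmin + 1) * (a.ymax - a.ymin + 1)
    area_b = (b.xmax - b.xmin + 1) * (b.ymax - b.ymin + 1)
    return inter / (area_a + area_b - inter)


def match_detections(preds, truths, iou_min: float = 0.5) -> MatchResult:
    """Greedily match predictions to truths on one image.

    Predictions are taken in descending score order (unscored treated as
    score 1, input order preserved); each takes the highest-IoU unmatched
    truth of the same label with IoU ≥ *iou_min*.  Each truth and each
    prediction is matched at most once.
    """
    order = sorted(range(len(preds)),
                   key=lambda i: -(preds[i].score if preds[i].score is not None else 1.0))
    taken = [False] * len(truths)
    pairs = []
    unmatched_p = []
    for i in order:
        p = preds[i]
        best_j, best_iou = -1, 0.0
        for j, tr in enumerate(truths):
            if taken[j] or tr.label != p.label:
                continue
            v = iou(p, tr)
            if v >= iou_min and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            pairs.append((p, truths[best_j], best_iou))
        else:
            unmatched_p.append(p)
    unmatched_t = [t for j, t in enumerate(truths) if not taken[j]]
    return MatchResult(pairs=pairs, unmatched_predictions=unmatched_p,
                       unmatched_truths=unmatched_t)


def evaluate(pred_sets: dict, truth_sets: dict, iou_min: float = 0.5) -> EvalReport:
    """Score per-image prediction boxes against per-image truth boxes.

    Both arguments map an image key to a box list; every predicted image
    must exist on the truth side.  ``mean_iou`` averages over matched pairs;
    ``feature_accuracy`` is the matched-truth fraction (how much of the
    annotated feature set was detected).
    """
    extra = set(pred_sets) - set(truth_sets)
    if extra:
        raise ValueError(f"images present in predictions but not truths: {sorted(extra)[:5]}")

    tp = fp = fn = 0
    ious = []
    per_class: dict = {}
    for key in sorted(truth_sets, key=str):
        preds = pred_sets.get(key, [])
        truths = truth_sets[key]
        m = match_detections(preds, truths, iou_min)
        tp += len(m.pairs)
        fp += len(m.unmatched_predictions)
        fn += len(m.unmatched_truths)
        ious.extend(v for _, _, v in m.pairs)
        for p, t, v in m.pairs:
            c = per_class.setdefault(t.label, {"tp": 0, "fp": 0, "fn": 0})
            c["tp"] += 1
        for p in m.unmatched_predictions:
            per_class.setdefault(p.label, {"tp": 0, "fp": 0, "fn": 0})["fp"] += 1
        for t in m.unmatched_truths:
            per_class.setdefault(t.label, {"tp": 0, "fp": 0, "fn": 0})["fn"] += 1

    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = tp / (tp + fn) if tp + fn else 0.0
    for c in per_class.values():
        c["precision"] = c["tp"] / (c["tp"] + c["fp"]) if c["tp"] + c["fp"] else 0.0
        c["recall"] = c["tp"] / (c["tp"] + c["fn"]) if c["tp"] + c["fn"] else 0.0

    return EvalReport(
        mean_iou=float(np.mean(ious)) if ious else 0.0,
        precision=precision, recall=recall, feature_accuracy=accuracy,
        per_class=per_class, n_true=tp + fn, n_pred=tp + fp, n_matched=tp,
    )
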
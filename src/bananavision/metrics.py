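"""Object-detection evaluation: IoU matching, precision/recall, AP, mAP, F1.

Definitions follow the single-stage-detector convention: greedy one-to-one
matching of detections to ground truths in descending confidence order at an
IoU threshold (default 0.5), average precision by all-points interpolation
of the precision-recall curve, mAP as the mean of per-class AP, and F1 as
the harmonic mean of precision and recall.  Also provides the printed-value
arithmetic (F1 from a published P/R pair, percent relative change) used to
audit reported benchmark tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .localizer import BoundingBox

__all__ = [
    "MatchResult",
    "PRCurve",
    "MetricsReport",
    "iou",
    "match",
    "precision_recall",
    "pr_curve",
    "average_precision",
    "f1",
    "relative_change",
    "evaluate",
]


@dataclass(frozen=True)
class MatchResult:
    """Per-detection TP/FP flags, ordered by descending confidence."""

    tp: np.ndarray  # bool, one per detection (confidence-ordered)
    confidences: np.ndarray
    n_gt: int

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


@dataclass(frozen=True)
class PRCurve:
    """Cumulative precision/recall along the confidence ranking."""

    precision: np.ndarray
    recall: np.ndarray


@dataclass(frozen=True)
class MetricsReport:
    """Evaluation summary: per-class AP plus pooled P/R/F1 and mAP."""

    precision: float
    recall: float
    ap_per_class: dict[int, float]
    map: float
    f1: float
    zero_division_flag: bool = False


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match(
    dets: Sequence[BoundingBox],
    gts: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ordered one-to-one matching within one image/class.

    Each detection, taken in descending confidence, is a TP if its best-IoU
    still-unmatched ground truth clears the threshold, else an FP; each
    ground truth can match at most once.  Confidence ties are broken by
    larger best-IoU, then input order.
    """
    if not dets:
        return MatchResult(
            tp=np.zeros(0, dtype=bool), confidences=np.zeros(0), n_gt=len(gts)
        )
    best_iou = [max((iou(d, g) for g in gts), default=0.0) for d in dets]
    order = sorted(
        range(len(dets)), key=lambda i: (-dets[i].confidence, -best_iou[i], i)
    )
    matched = [False] * len(gts)
    tp = np.zeros(len(dets), dtype=bool)
    conf = np.zeros(len(dets))
    for rank, i in enumerate(order):
        conf[rank] = dets[i].confidence
        best_j, best = -1, 0.0
        for j, g in enumerate(gts):
            if matched[j]:
                continue
            v = iou(dets[i], g)
            if v > best:
                best, best_j = v, j
        if best_j >= 0 and best >= iou_threshold:
            matched[best_j] = True
            tp[rank] = True
    return MatchResult(tp=tp, confidences=conf, n_gt=len(gts))


def precision_recall(m: MatchResult) -> tuple[float, float, bool]:
    """Overall (P, R) of a match, with a 0/0 flag.

    P = TP/(TP+FP), R = TP/(TP+FN); an empty denominator yields 0 and sets
    the flag instead of raising.
    """
    flag = False
    n_det = m.n_tp + m.n_fp
    if n_det == 0:
        p, flag = 0.0, True
    else:
        p = m.n_tp / n_det
    if m.n_gt == 0:
        r, flag = 0.0, True
    else:
        r = m.n_tp / m.n_gt
    return p, r, flag


def pr_curve(m: MatchResult) -> PRCurve:
    """Cumulative PR curve along the confidence-ordered detections."""
    tp_cum = np.cumsum(m.tp)
    fp_cum = np.cumsum(~m.tp)
    denom = tp_cum + fp_cum
    precision = np.where(denom > 0, tp_cum / np.maximum(denom, 1), 0.0)
    recall = tp_cum / m.n_gt if m.n_gt > 0 else np.zeros_like(tp_cum, dtype=float)
    return PRCurve(precision=precision, recall=recall)


def average_precision(curve: PRCurve) -> float:
    """All-points interpolated AP: area under the precision envelope.

    AP = sum over recall steps of (R_i - R_{i-1}) * max precision at
    recall >= R_i.  An empty curve scores 0.
    """
    if curve.recall.size == 0:
        return 0.0
    r = np.concatenate([[0.0], curve.recall, [curve.recall[-1]]])
    p = np.concatenate([[0.0], curve.precision, [0.0]])
    # precision envelope: running max from the right
    p = np.maximum.accumulate(p[::-1])[::-1]
    steps = np.flatnonzero(np.diff(r) > 0)
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def f1(P: float, R: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when P + R = 0."""
    if not (0 <= P <= 1 and 0 <= R <= 1):
        raise ValueError(f"P and R must lie in [0, 1], got {P}, {R}")
    return 0.0 if P + R == 0 else 2 * P * R / (P + R)


def relative_change(new: float, old: float) -> float:
    """Percent change 100*(new - old)/old, rounded to 2 decimals."""
    if old == 0:
        raise ZeroDivisionError("relative change undefined for a zero baseline")
    return round(100.0 * (new - old) / old, 2)


def _merge_matches(per_image: list[MatchResult]) -> MatchResult:
    """Pool per-image matches into one confidence-ranked result."""
    tp = np.concatenate([m.tp for m in per_image]) if per_image else np.zeros(0, bool)
    conf = np.concatenate([m.confidences for m in per_image]) if per_image else np.zeros(0)
    order = np.argsort(-conf, kind="stable")
    return MatchResult(tp=tp[order], confidences=conf[order], n_gt=sum(m.n_gt for m in per_image))


def evaluate(
    detections: Sequence[Sequence[BoundingBox]],
    ground_truths: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
) -> MetricsReport:
    """Dataset-level evaluation: per-class AP, mAP over classes, pooled P/R/F1.

    ``detections[i]`` and ``ground_truths[i]`` are the boxes of image ``i``.
    Classes are taken from the boxes' ``class_id``; single-class data yields
    mAP = AP of that class.
    """
    if len(detections) != len(ground_truths):
        raise ValueError("detections and ground_truths must cover the same images")
    classes = sorted(
        {b.class_id for img in ground_truths for b in img}
        | {b.class_id for img in detections for b in img}
    ) or [0]
    ap_per_class: dict[int, float] = {}
    pooled: list[MatchResult] = []
    for c in classes:
        per_image = [
            match(
                [d for d in dets if d.class_id == c],
                [g for g in gts if g.class_id == c],
                iou_threshold,
            )
            for dets, gts in zip(detections, ground_truths)
        ]
        merged = _merge_matches(per_image)
        ap_per_class[c] = average_precision(pr_curve(merged))
        pooled.append(merged)
    all_merged = _merge_matches(pooled)
    P, R, flag = precision_recall(all_merged)
    return MetricsReport(
        precision=P,
        recall=R,
        ap_per_class=ap_per_class,
        map=float(np.mean(list(ap_per_class.values()))),
        f1=f1(P, R),
        zero_division_flag=flag,
    )
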
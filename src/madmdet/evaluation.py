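"""Object-detection evaluation: greedy IoU matching, precision/recall/F1,
interpolated-PR average precision, and workflow-level reports.

Matching follows the standard single-IoU protocol: predictions of a class
are processed in descending confidence order; each is matched greedily to
the not-yet-matched ground-truth box of highest IoU, and counts as a true
positive only when that IoU is strictly above the threshold (default 0.5).
A ground-truth object can be matched at most once — a second, redundant hit
on the same object is a false positive.

Average precision is the area under the *adjusted* precision-recall curve:
cumulative precision/recall pairs are computed at every confidence rank,
each precision is replaced by the maximum precision attained at an equal or
higher recall, and the resulting step function is integrated over recall
(all-point interpolation, not 11-point sampling).  The multiclass score is
the unweighted mean of per-class APs.

Confidence ties are broken by stable input order so every quantity is
deterministic, and AP depends on confidences only through their ranking, so
any strictly increasing rescaling of confidences leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotations import (
    CellClass,
    Detection,
    GroundTruthRecord,
    iou,
    scheme_classes,
)

__all__ = [
    "MatchResult",
    "PRCurve",
    "APReport",
    "match",
    "precision_recall_f1",
    "pr_curve",
    "average_precision",
    "evaluate_workflow",
    "plot_pr_curve",
]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one class's predictions against ground truth.

    ``verdicts`` is ordered by confidence rank (stable for ties) and pairs
    each prediction's original index with whether it was a true positive.
    """

    tp: int
    fp: int
    fn: int
    verdicts: tuple[tuple[int, bool], ...]
    gt_matched: tuple[bool, ...]


@dataclass(frozen=True)
class PRCurve:
    """Cumulative precision/recall pairs along the confidence rank."""

    recalls: tuple[float, ...]
    precisions: tuple[float, ...]
    adjusted_precisions: tuple[float, ...]


@dataclass(frozen=True)
class APReport:
    """Per-class AP and F-scores plus their unweighted means."""

    per_class_ap: Mapping[str, float]
    per_class_f1: Mapping[str, float]
    mean_ap: float
    mean_f1: float
    per_class_counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class_ap": dict(self.per_class_ap),
            "per_class_f1": dict(self.per_class_f1),
            "mean_ap": self.mean_ap,
            "mean_f1": self.mean_f1,
            "per_class_counts": {k: dict(v) for k, v in self.per_class_counts.items()},
        }


def _rank(predictions: Sequence[Detection]) -> list[int]:
    return sorted(range(len(predictions)), key=lambda i: (-predictions[i].confidence, i))


def match(
    predictions: Sequence[Detection],
    ground_truth: Sequence[GroundTruthRecord],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ranked matching of predictions to ground truth.

    The caller is expected to pass a single class's predictions and ground
    truth (matching is per class).
    """
    matched = [False] * len(ground_truth)
    verdicts: list[tuple[int, bool]] = []
    tp = 0
    for pi in _rank(predictions):
        best_iou, best_gt = 0.0, -1
        for gi, gt in enumerate(ground_truth):
            if matched[gi]:
                continue
            val = iou(predictions[pi].box, gt.box)
            if val > best_iou:
                best_iou, best_gt = val, gi
        hit = best_gt >= 0 and best_iou > iou_threshold
        if hit:
            matched[best_gt] = True
            tp += 1
        verdicts.append((pi, hit))
    fp = len(predictions) - tp
    fn = len(ground_truth) - tp
    return MatchResult(tp, fp, fn, tuple(verdicts), tuple(matched))


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Precision, recall, and their harmonic mean.

    Conventions for degenerate inputs: precision is 0 with no predictions,
    recall is 0 with no ground truth, and F1 is 0 when P + R = 0.
    """
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else 0.0
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def pr_curve(
    predictions: Sequence[Detection],
    ground_truth: Sequence[GroundTruthRecord],
    iou_threshold: float = 0.5,
) -> PRCurve:
    """Cumulative PR pairs at every rank plus the interpolated precision."""
    if not ground_truth:
        raise ValueError("PR curve undefined without ground-truth objects")
    m = match(predictions, ground_truth, iou_threshold)
    n_gt = len(ground_truth)
    recalls, precisions = [], []
    cum_tp = 0
    for k, (_pi, hit) in enumerate(m.verdicts, start=1):
        cum_tp += int(hit)
        recalls.append(cum_tp / n_gt)
        precisions.append(cum_tp / k)
    adjusted = list(precisions)
    for i in range(len(adjusted) - 2, -1, -1):
        adjusted[i] = max(adjusted[i], adjusted[i + 1])
    return PRCurve(tuple(recalls), tuple(precisions), tuple(adjusted))


def average_precision(
    predictions: Sequence[Detection],
    ground_truth: Sequence[GroundTruthRecord],
    iou_threshold: float = 0.5,
) -> float:
    """Area under the adjusted precision-recall curve, in [0, 1]."""
    curve = pr_curve(predictions, ground_truth, iou_threshold)
    ap = 0.0
    prev_recall = 0.0
    for r, p_adj in zip(curve.recalls, curve.adjusted_precisions):
        if r > prev_recall:
            ap += (r - prev_recall) * p_adj
            prev_recall = r
    return ap


def evaluate_workflow(
    merged_predictions: Sequence[Detection],
    merged_gt: Sequence[GroundTruthRecord],
    class_scheme: str = "seven",
    iou_threshold: float = 0.5,
    f1_confidence: float = 0.5,
) -> APReport:
    """Per-class AP and F1 over a class scheme, plus unweighted means.

    AP uses all predictions ranked by confidence; F-scores are computed
    after filtering predictions at confidence > ``f1_confidence`` (the
    display threshold).  Classes without ground truth are excluded from the
    AP mean (AP is undefined there) but still contribute an F1 of 0 if they
    have predictions.
    """
    classes = scheme_classes(class_scheme)
    valid = set(classes)
    for det in merged_predictions:
        if det.label not in valid:
            raise ValueError(
                f"prediction class {det.label.name!r} absent from the "
                f"{class_scheme}-class scheme"
            )
    for rec in merged_gt:
        if rec.label not in valid:
            raise ValueError(
                f"ground-truth class {rec.label.name!r} absent from the "
                f"{class_scheme}-class scheme"
            )

    per_ap: dict[str, float] = {}
    per_f1: dict[str, float] = {}
    per_counts: dict[str, dict[str, int]] = {}
    for cls in classes:
        preds = [d for d in merged_predictions if d.label == cls]
        gts = [r for r in merged_gt if r.label == cls]
        if gts:
            per_ap[cls.name] = average_precision(preds, gts, iou_threshold)
        shown = [d for d in preds if d.confidence > f1_confidence]
        if not gts and not shown:
            continue
        m = match(shown, gts, iou_threshold)
        _p, _r, f1 = precision_recall_f1(m)
        per_f1[cls.name] = f1
        per_counts[cls.name] = {"tp": m.tp, "fp": m.fp, "fn": m.fn}

    mean_ap = float(np.mean(list(per_ap.values()))) if per_ap else 0.0
    mean_f1 = float(np.mean(list(per_f1.values()))) if per_f1 else 0.0
    return APReport(per_ap, per_f1, mean_ap, mean_f1, per_counts)


def plot_pr_curve(curve: PRCurve, path, title: str = "precision-recall"):
    """Write the raw and adjusted PR curves as a plot image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.recalls, curve.precisions, ".-", label="raw", alpha=0.6)
    ax.step(
        curve.recalls, curve.adjusted_precisions, where="post", label="adjusted"
    )
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
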
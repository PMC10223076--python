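"""Detection, tracking, and counting evaluation.

Detection metrics: precision, recall (percent), average precision by
all-point interpolation (area under the precision envelope over recall) and
its mean over classes. Tracking metrics: per-frame ground-truth/hypothesis
matching with persistent pairings for ID-switch detection, and count-based
MOTA = 1 - (sum FN + FP + IDS) / sum GT_t. Counting metrics: per-video L1
loss and accuracy, summarized as mean L1 plus the accuracy range.

Miss and false-detection *rates* (FN/(FN+TP), FP/(FP+TN)) are exposed for
reporting alongside the count-based MOTA; when no explicit negatives exist
the false-detection rate falls back to FP/(FP+TP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import BoundingBox, iou
from .tracker import CountReport, count_report
from . import association as assoc

__all__ = [
    "ConfusionCounts",
    "MotTally",
    "PrCurve",
    "UndefinedMetricError",
    "precision_recall",
    "miss_rate",
    "false_detection_rate",
    "average_precision",
    "mean_ap",
    "pr_curve_from_ranking",
    "FrameMatcher",
    "match_frame",
    "mota",
    "evaluate_tracking",
    "counting_table",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the value is absent, not 0."""


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), both as percentages."""
    if counts.TP + counts.FP == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    if counts.TP + counts.FN == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    p = 100.0 * counts.TP / (counts.TP + counts.FP)
    r = 100.0 * counts.TP / (counts.TP + counts.FN)
    return p, r


def miss_rate(counts: ConfusionCounts) -> float:
    """FN / (FN + TP), percent."""
    if counts.FN + counts.TP == 0:
        raise UndefinedMetricError("miss rate undefined")
    return 100.0 * counts.FN / (counts.FN + counts.TP)


def false_detection_rate(counts: ConfusionCounts) -> float:
    """FP / (FP + TN), percent; FP / (FP + TP) when no negatives exist."""
    denom = counts.FP + (counts.TN if counts.TN > 0 else counts.TP)
    if denom == 0:
        raise UndefinedMetricError("false detection rate undefined")
    return 100.0 * counts.FP / denom


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------

@dataclass
class PrCurve:
    """(recall, precision) points from confidence-ranked detections."""

    recall: np.ndarray
    precision: np.ndarray

    def __post_init__(self):
        self.recall = np.asarray(self.recall, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if self.recall.shape != self.precision.shape:
            raise ValueError("recall/precision length mismatch")
        if np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing along the ranking")


def pr_curve_from_ranking(outcomes, n_groundtruth: int) -> PrCurve:
    """Curve from a confidence-ranked list of detection outcomes
    (True = TP, False = FP) against ``n_groundtruth`` objects."""
    if n_groundtruth < 1:
        raise UndefinedMetricError("AP undefined without ground-truth objects")
    outcomes = np.asarray(outcomes, dtype=bool)
    tp = np.cumsum(outcomes)
    ranks = np.arange(1, len(outcomes) + 1)
    return PrCurve(recall=tp / n_groundtruth, precision=tp / ranks)


def average_precision(curve: PrCurve) -> float:
    """All-point interpolated AP: area under the precision envelope.

    The envelope at recall r is the maximum precision at any recall >= r;
    the area is the sum of envelope precision times recall increments.
    """
    r = np.concatenate([[0.0], curve.recall])
    p = np.concatenate([[0.0], curve.precision])
    envelope = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum(np.diff(r) * envelope[1:]))


def mean_ap(per_class: list[float]) -> float:
    """Arithmetic mean of per-class AP values."""
    if not per_class:
        raise UndefinedMetricError("mAP undefined with no classes")
    return float(np.mean(per_class))


# ---------------------------------------------------------------------------
# Tracking evaluation
# ---------------------------------------------------------------------------

@dataclass
class MotTally:
    """Accumulated per-frame error counts for MOTA."""

    FN: int = 0
    FP: int = 0
    IDS: int = 0
    GT: int = 0
    matches: int = 0

    def __iadd__(self, other: "MotTally") -> "MotTally":
        self.FN += other.FN
        self.FP += other.FP
        self.IDS += other.IDS
        self.GT += other.GT
        self.matches += other.matches
        return self


@dataclass
class FrameMatchResult:
    matches: list[tuple[int, int]]   # (gt id, hyp id)
    tally: MotTally


class FrameMatcher:
    """Per-frame gt/hypothesis matching with ID-switch bookkeeping.

    Matching is minimum-cost bipartite on 1 - IoU, pairs above the distance
    threshold inadmissible. The matcher remembers each ground-truth object's
    last matched hypothesis ID; a new match with a different ID counts one
    ID switch.
    """

    def __init__(self, iou_threshold: float = 0.5):
        self.distance_threshold = 1.0 - iou_threshold
        self._last_hyp: dict[int, int] = {}
        self.tally = MotTally()

    def step(
        self,
        gt: list[tuple[int, BoundingBox]],
        hyp: list[tuple[int, BoundingBox]],
    ) -> FrameMatchResult:
        n_g, n_h = len(gt), len(hyp)
        values = np.ones((n_g, n_h))
        for i, (_, gb) in enumerate(gt):
            for j, (_, hb) in enumerate(hyp):
                values[i, j] = 1.0 - iou(gb, hb)
        mask = values <= self.distance_threshold
        res = assoc.solve_assignment(assoc.CostMatrix(values, mask)) \
            if n_g and n_h else assoc.AssociationResult(
                [], list(range(n_g)), list(range(n_h)))
        matches = [(gt[i][0], hyp[j][0]) for i, j in res.matches]
        ids = 0
        for gt_id, hyp_id in matches:
            prev = self._last_hyp.get(gt_id)
            if prev is not None and prev != hyp_id:
                ids += 1
            self._last_hyp[gt_id] = hyp_id
        frame_tally = MotTally(
            FN=len(res.unmatched_tracks),
            FP=len(res.unmatched_detections),
            IDS=ids,
            GT=n_g,
            matches=len(matches),
        )
        self.tally += frame_tally
        return FrameMatchResult(matches=matches, tally=frame_tally)


def match_frame(gt, hyp, iou_threshold: float = 0.5) -> FrameMatchResult:
    """Single-frame matching without cross-frame state (no ID switches)."""
    return FrameMatcher(iou_threshold).step(gt, hyp)


def mota(tally: MotTally) -> float:
    """Count-based MOTA = 1 - (FN + FP + IDS) / GT; may be negative."""
    if tally.GT <= 0:
        raise UndefinedMetricError("MOTA undefined: no ground-truth objects")
    return 1.0 - (tally.FN + tally.FP + tally.IDS) / tally.GT


def evaluate_tracking(
    gt_by_frame: dict[int, list[tuple[int, BoundingBox]]],
    hyp_by_frame: dict[int, list[tuple[int, BoundingBox]]],
    iou_threshold: float = 0.5,
) -> dict:
    """Run the frame matcher over a whole video and report MOTA and rates."""
    matcher = FrameMatcher(iou_threshold)
    for frame in sorted(set(gt_by_frame) | set(hyp_by_frame)):
        matcher.step(gt_by_frame.get(frame, []), hyp_by_frame.get(frame, []))
    t = matcher.tally
    counts = ConfusionCounts(TP=t.matches, FP=t.FP, FN=t.FN)
    report = {
        "mota": mota(t),
        "ids": t.IDS,
        "fn": t.FN,
        "fp": t.FP,
        "gt": t.GT,
    }
    try:
        p, r = precision_recall(counts)
        report["precision"] = p
        report["recall"] = r
        report["miss_rate"] = miss_rate(counts)
        report["false_detection_rate"] = false_detection_rate(counts)
    except UndefinedMetricError:
        pass
    return report


# ---------------------------------------------------------------------------
# Counting evaluation
# ---------------------------------------------------------------------------

def counting_table(reports: list[CountReport]) -> dict:
    """Summarize per-video counting reports: mean L1, accuracy range."""
    if not reports:
        raise ValueError("no reports to summarize")
    for rep in reports:
        if rep.true_count is None:
            raise ValueError("every report needs ground truth")
    l1 = [rep.l1_loss for rep in reports]
    acc = [rep.accuracy_percent for rep in reports]
    return {
        "mean_l1": float(np.mean(l1)),
        "accuracy_min": float(min(acc)),
        "accuracy_max": float(max(acc)),
        "per_video": [
            {
                "predicted": rep.predicted_count,
                "true": rep.true_count,
                "l1": rep.l1_loss,
                "accuracy": rep.accuracy_percent,
            }
            for rep in reports
        ],
    }
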
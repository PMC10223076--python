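"""Track-detection association: appearance gallery distance, dual gating,
combined cost, Hungarian assignment, age-prioritized matching cascade, and
IoU fallback matching.

The motion gate is the squared Mahalanobis distance of a detection from a
track's predicted state, thresholded at the chi-square 0.95 quantile for 4
degrees of freedom (9.4877). The appearance gate is the minimum cosine
distance between the detection embedding and the track's feature gallery,
thresholded at ``max_dist``. A pair is admissible only when both gates pass;
the assignment cost is the convex combination
``lambda * d_motion + (1 - lambda) * d_appearance``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

from .geometry import iou

__all__ = [
    "CHI2_GATE_4DOF",
    "GATED_COST",
    "Gallery",
    "CostMatrix",
    "AssociationResult",
    "EmptyGalleryError",
    "cosine_gallery_distance",
    "motion_gate",
    "appearance_gate",
    "combined_cost",
    "solve_assignment",
    "matching_cascade",
    "iou_match",
]

#: 0.95 quantile of chi-square with 4 dof — the motion gate on a 4-dim
#: squared Mahalanobis distance.
CHI2_GATE_4DOF: float = float(scipy.stats.chi2.ppf(0.95, df=4))

#: Sentinel cost for inadmissible pairs; larger than any admissible cost.
GATED_COST: float = 1e5


class EmptyGalleryError(RuntimeError):
    """No appearance features stored yet; caller falls back to motion only."""


class Gallery:
    """Bounded per-track queue of past unit-norm appearance embeddings.

    Vectors are re-normalized at insertion, so stored features always satisfy
    the unit-norm constraint regardless of upstream rounding.
    """

    def __init__(self, capacity: int = 100):
        if capacity < 1:
            raise ValueError("gallery capacity must be >= 1")
        self.capacity = capacity
        self._features: deque[np.ndarray] = deque(maxlen=capacity)

    def add(self, feature: np.ndarray) -> None:
        feature = np.asarray(feature, dtype=float)
        norm = np.linalg.norm(feature)
        if norm == 0:
            raise ValueError("cannot store a zero feature vector")
        self._features.append(feature / norm)

    def __len__(self) -> int:
        return len(self._features)

    def as_matrix(self) -> np.ndarray:
        if not self._features:
            raise EmptyGalleryError("gallery is empty")
        return np.stack(self._features)


def cosine_gallery_distance(gallery: Gallery, r: np.ndarray) -> float:
    """Minimum cosine distance min_k (1 - r^T r_k) over the stored gallery."""
    r = np.asarray(r, dtype=float)
    if abs(np.linalg.norm(r) - 1.0) > 1e-6:
        raise ValueError("query embedding must be unit-norm")
    sims = gallery.as_matrix() @ r
    return float(1.0 - sims.max())


def motion_gate(d1: float, t1: float = CHI2_GATE_4DOF) -> bool:
    """Inclusive Mahalanobis gate: admissible iff d1 <= t1."""
    if t1 <= 0:
        raise ValueError("threshold must be positive")
    return d1 <= t1


def appearance_gate(d2: float, t2: float) -> bool:
    """Inclusive cosine gate: admissible iff d2 <= t2."""
    if t2 <= 0:
        raise ValueError("threshold must be positive")
    return d2 <= t2


def combined_cost(d1: float, d2: float, lam: float) -> float:
    """C = lambda * d1 + (1 - lambda) * d2, lambda in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam * d1 + (1.0 - lam) * d2


@dataclass
class CostMatrix:
    """Tracks x detections cost values plus the admissibility mask."""

    values: np.ndarray
    gate_mask: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.gate_mask = np.atleast_2d(np.asarray(self.gate_mask, dtype=bool))
        if self.values.shape != self.gate_mask.shape:
            raise ValueError("values and gate_mask shapes differ")
        if not np.all(np.isfinite(self.values[self.gate_mask])):
            raise ValueError("admissible costs must be finite")

    def gated_values(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.gate_mask] = GATED_COST
        return out


@dataclass
class AssociationResult:
    matches: list[tuple[int, int]] = field(default_factory=list)
    unmatched_tracks: list[int] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)


def solve_assignment(cost: CostMatrix) -> AssociationResult:
    """Minimum-total-cost one-to-one assignment over admissible pairs.

    Hungarian assignment on the gated matrix; pairs carrying the gate
    sentinel are stripped from the solution afterwards, so a gated pair can
    never appear in the matches. Ties break toward the lexicographically
    smallest (track, detection) pair by the solver's row-major scan order.
    """
    n_tracks, n_dets = cost.values.shape
    if n_tracks == 0 or n_dets == 0:
        return AssociationResult(
            matches=[],
            unmatched_tracks=list(range(n_tracks)),
            unmatched_detections=list(range(n_dets)),
        )
    values = cost.gated_values()
    rows, cols = scipy.optimize.linear_sum_assignment(values)
    matches = [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if cost.gate_mask[r, c]
    ]
    matched_t = {t for t, _ in matches}
    matched_d = {d for _, d in matches}
    return AssociationResult(
        matches=sorted(matches),
        unmatched_tracks=[t for t in range(n_tracks) if t not in matched_t],
        unmatched_detections=[d for d in range(n_dets) if d not in matched_d],
    )


def matching_cascade(
    cost_fn,
    track_ages: list[int],
    n_detections: int,
    max_age_levels: int,
) -> AssociationResult:
    """Age-prioritized association: recently updated tracks match first.

    Iterates age levels 0..max_age_levels-1; at each level the tracks whose
    time-since-update equals level+1 compete (via ``cost_fn``) for the
    detections still unmatched. ``cost_fn(track_subset, det_subset)`` must
    return a :class:`CostMatrix` restricted to those indices.

    ``track_ages`` holds each track's time-since-update after prediction
    (>= 1 for every live track).
    """
    unmatched_dets = list(range(n_detections))
    matches: list[tuple[int, int]] = []
    for level in range(max_age_levels):
        if not unmatched_dets:
            break
        level_tracks = [i for i, a in enumerate(track_ages) if a == level + 1]
        if not level_tracks:
            continue
        sub = cost_fn(level_tracks, unmatched_dets)
        res = solve_assignment(sub)
        matches.extend(
            (level_tracks[ti], unmatched_dets[di]) for ti, di in res.matches
        )
        unmatched_dets = [unmatched_dets[di] for di in res.unmatched_detections]
    matched_t = {t for t, _ in matches}
    return AssociationResult(
        matches=sorted(matches),
        unmatched_tracks=[t for t in range(len(track_ages)) if t not in matched_t],
        unmatched_detections=unmatched_dets,
    )


def iou_match(track_boxes, det_boxes, max_iou_distance: float = 0.8) -> AssociationResult:
    """Hungarian assignment on cost 1 - IoU; pairs with cost strictly above
    ``max_iou_distance`` are inadmissible."""
    n_t, n_d = len(track_boxes), len(det_boxes)
    values = np.ones((n_t, n_d))
    for i, tb in enumerate(track_boxes):
        for j, db in enumerate(det_boxes):
            values[i, j] = 1.0 - iou(tb, db)
    mask = values <= max_iou_distance
    return solve_assignment(CostMatrix(values, mask))
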
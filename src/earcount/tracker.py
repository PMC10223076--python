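"""Track lifecycle, the per-frame tracker step, and unique-ID counting.

A tracker run turns a per-frame detection stream into identity-preserving
tracks; the abundance estimate for the video is the number of distinct track
IDs that ever reached confirmed status. Tentative tracks need ``n_init``
consecutive hits to confirm, which is what keeps short-lived false positives
out of the count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import association as assoc
from .geometry import BoundingBox, Detection, filter_confidence, nms
from .kalman import KalmanFilter, KalmanState, box_to_measurement, measurement_to_box

__all__ = [
    "TrackStatus",
    "Track",
    "TrackerConfig",
    "Tracker",
    "CountReport",
    "count_unique_ids",
    "count_report",
    "run_tracker",
]

logger = logging.getLogger(__name__)

TENTATIVE = "tentative"
CONFIRMED = "confirmed"
DELETED = "deleted"
TrackStatus = str


@dataclass
class TrackerConfig:
    """Tracker thresholds. YAML keys mirror the conventional upper-case
    parameter names (MAX_DIST, MIN_CONFIDENCE, NMS_MAX_OVERLAP,
    MAX_IOU_DISTANCE, N_INIT, MAX_AGE, LAMBDA, GALLERY_SIZE)."""

    min_confidence: float = 0.2
    nms_max_overlap: float = 0.5
    max_dist: float = 0.3          # appearance gate t2 on cosine distance
    max_iou_distance: float = 0.8
    n_init: int = 5
    max_age: int = 100
    lambda_weight: float = 0.0     # motion weight in the combined cost
    gallery_size: int = 100
    motion_gate_threshold: float = assoc.CHI2_GATE_4DOF

    def __post_init__(self):
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        for name in ("min_confidence", "nms_max_overlap", "max_dist",
                     "max_iou_distance", "lambda_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= (2.0 if name == "max_dist" else 1.0):
                raise ValueError(f"{name}={v} out of range")

    _YAML_KEYS = {
        "MAX_DIST": "max_dist",
        "MIN_CONFIDENCE": "min_confidence",
        "NMS_MAX_OVERLAP": "nms_max_overlap",
        "MAX_IOU_DISTANCE": "max_iou_distance",
        "N_INIT": "n_init",
        "MAX_AGE": "max_age",
        "LAMBDA": "lambda_weight",
        "GALLERY_SIZE": "gallery_size",
    }

    @classmethod
    def from_yaml(cls, path) -> "TrackerConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            attr = cls._YAML_KEYS.get(key.upper(), key.lower())
            kwargs[attr] = value
        return cls(**kwargs)


@dataclass
class Track:
    """One tracked identity: Kalman state, appearance gallery, lifecycle."""

    track_id: int
    state: KalmanState
    gallery: assoc.Gallery
    status: TrackStatus = TENTATIVE
    hits: int = 1
    time_since_update: int = 0

    def to_box(self) -> BoundingBox:
        return measurement_to_box(self.state.mean[:4])

    @property
    def is_confirmed(self) -> bool:
        return self.status == CONFIRMED


@dataclass
class TrackSnapshot:
    """Per-frame output row for a confirmed track (predicted box)."""

    frame: int
    track_id: int
    box: BoundingBox


@dataclass
class CountReport:
    predicted_count: int
    true_count: Optional[int] = None
    l1_loss: Optional[int] = None
    accuracy_percent: Optional[float] = None


def _round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return np.floor(x * factor + 0.5) / factor


def count_report(predicted: int, true: Optional[int]) -> CountReport:
    """L1 loss |predicted - true| and accuracy 100*(1 - L1/true), which for
    undercounts equals 100*predicted/true. Accuracy is rounded half-up to
    one decimal."""
    if true is None:
        return CountReport(predicted_count=predicted)
    if true <= 0:
        raise ValueError("ground-truth count must be positive")
    l1 = abs(predicted - true)
    acc = _round_half_up(100.0 * (1.0 - l1 / true))
    return CountReport(predicted, true, l1, acc)


def count_unique_ids(track_history) -> int:
    """Number of distinct track IDs that ever reached confirmed status.

    ``track_history`` is any iterable of :class:`TrackSnapshot` (only
    confirmed tracks are ever emitted) or of ``(frame, track_id, ...)`` rows.
    """
    ids = set()
    for item in track_history:
        ids.add(item.track_id if hasattr(item, "track_id") else item[1])
    return len(ids)


class Tracker:
    """Frame-by-frame multi-object tracker.

    Per frame: predict every live track forward; cascade-match confirmed
    tracks against detections using the gated combined cost; IoU-match the
    unconfirmed tracks plus the just-missed (time-since-update 1) cascade
    leftovers; Kalman-update and gallery-append matched tracks; spawn
    tentative tracks for leftover detections; age out the rest.
    """

    def __init__(self, config: Optional[TrackerConfig] = None):
        self.config = config or TrackerConfig()
        self.kf = KalmanFilter()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame = 0
        self.confirmed_ids: set[int] = set()

    # -- cost construction --------------------------------------------------

    def _gated_cost(self, tracks: list[Track], dets: list[Detection]) -> assoc.CostMatrix:
        cfg = self.config
        n_t, n_d = len(tracks), len(dets)
        values = np.full((n_t, n_d), assoc.GATED_COST)
        mask = np.zeros((n_t, n_d), dtype=bool)
        measurements = np.stack([box_to_measurement(d.box) for d in dets])
        for i, trk in enumerate(tracks):
            d1 = self.kf.gating_distance(trk.state, measurements)
            for j, det in enumerate(dets):
                if not assoc.motion_gate(d1[j], cfg.motion_gate_threshold):
                    continue
                if det.embedding is not None and len(trk.gallery) > 0:
                    d2 = assoc.cosine_gallery_distance(trk.gallery, det.embedding)
                    if not assoc.appearance_gate(d2, cfg.max_dist):
                        continue
                    cost = assoc.combined_cost(d1[j], d2, cfg.lambda_weight)
                else:
                    # no appearance available: fall back to motion-only cost
                    cost = d1[j]
                values[i, j] = cost
                mask[i, j] = True
        return assoc.CostMatrix(values, mask)

    # -- lifecycle ----------------------------------------------------------

    def _initiate_track(self, det: Detection) -> Track:
        state = self.kf.initiate(box_to_measurement(det.box))
        gallery = assoc.Gallery(self.config.gallery_size)
        if det.embedding is not None:
            gallery.add(det.embedding)
        trk = Track(track_id=self._next_id, state=state, gallery=gallery)
        self._next_id += 1
        if trk.hits >= self.config.n_init:
            trk.status = CONFIRMED
            self.confirmed_ids.add(trk.track_id)
        return trk

    def _mark_hit(self, trk: Track, det: Detection) -> None:
        trk.state = self.kf.update(trk.state, box_to_measurement(det.box))
        if det.embedding is not None:
            trk.gallery.add(det.embedding)
        trk.hits += 1
        trk.time_since_update = 0
        if trk.status == TENTATIVE and trk.hits >= self.config.n_init:
            trk.status = CONFIRMED
            self.confirmed_ids.add(trk.track_id)

    def _mark_missed(self, trk: Track) -> None:
        if trk.status == TENTATIVE:
            trk.status = DELETED
        elif trk.time_since_update > self.config.max_age:
            trk.status = DELETED

    # -- the per-frame step -------------------------------------------------

    def step(self, frame: int, detections: list[Detection]) -> list[TrackSnapshot]:
        """Advance one frame and return confirmed-track snapshots.

        ``detections`` must all belong to ``frame`` and should already be
        confidence-filtered and NMS-suppressed (see :func:`run_tracker`).
        """
        if frame <= self._last_frame:
            raise ValueError(
                f"out-of-order frame {frame} (last processed {self._last_frame})"
            )
        self._last_frame = frame
        for det in detections:
            if det.frame != frame:
                raise ValueError("detection frame stamp does not match step frame")

        # 1. predict
        for trk in self.tracks:
            trk.state = self.kf.predict(trk.state)
            trk.time_since_update += 1

        confirmed = [t for t in self.tracks if t.status == CONFIRMED]
        unconfirmed = [t for t in self.tracks if t.status == TENTATIVE]

        # 2. cascade match confirmed tracks on the gated combined cost
        def cost_fn(track_idx, det_idx):
            sub_tracks = [confirmed[i] for i in track_idx]
            sub_dets = [detections[j] for j in det_idx]
            return self._gated_cost(sub_tracks, sub_dets)

        cascade = assoc.matching_cascade(
            cost_fn,
            [t.time_since_update for t in confirmed],
            len(detections),
            max_age_levels=self.config.max_age,
        )
        matches = [(confirmed[i], detections[j]) for i, j in cascade.matches]

        # 3. IoU match: unconfirmed tracks + cascade leftovers missed 1 frame
        iou_candidates = unconfirmed + [
            confirmed[i] for i in cascade.unmatched_tracks
            if confirmed[i].time_since_update == 1
        ]
        remaining_dets = list(cascade.unmatched_detections)
        iou_res = assoc.iou_match(
            [t.to_box() for t in iou_candidates],
            [detections[j].box for j in remaining_dets],
            self.config.max_iou_distance,
        )
        matches += [
            (iou_candidates[i], detections[remaining_dets[j]])
            for i, j in iou_res.matches
        ]
        unmatched_tracks = (
            [iou_candidates[i] for i in iou_res.unmatched_tracks]
            + [confirmed[i] for i in cascade.unmatched_tracks
               if confirmed[i].time_since_update != 1]
        )
        unmatched_dets = [remaining_dets[j] for j in iou_res.unmatched_detections]

        # 4. update / miss / spawn
        for trk, det in matches:
            self._mark_hit(trk, det)
        for trk in unmatched_tracks:
            self._mark_missed(trk)
        for j in unmatched_dets:
            self.tracks.append(self._initiate_track(detections[j]))
        self.tracks = [t for t in self.tracks if t.status != DELETED]

        logger.debug(
            "frame %d: %d dets, %d matches, %d new tracks, %d live",
            frame, len(detections), len(matches), len(unmatched_dets),
            len(self.tracks),
        )
        return [
            TrackSnapshot(frame, t.track_id, t.to_box())
            for t in self.tracks
            if t.status == CONFIRMED and t.time_since_update == 0
        ]


def run_tracker(
    detections_by_frame: dict[int, list[Detection]],
    config: Optional[TrackerConfig] = None,
) -> tuple[list[TrackSnapshot], Tracker]:
    """Run a full video: pre-filter each frame (confidence then NMS), step
    the tracker, and collect the confirmed-track history."""
    cfg = config or TrackerConfig()
    tracker = Tracker(cfg)
    history: list[TrackSnapshot] = []
    last = max(detections_by_frame, default=0)
    for frame in range(1, last + 1):
        dets = detections_by_frame.get(frame, [])
        dets = filter_confidence(dets, cfg.min_confidence)
        dets = nms(dets, cfg.nms_max_overlap)
        history.extend(tracker.step(frame, dets))
    return history, tracker
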
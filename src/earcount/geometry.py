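"""Bounding-box geometry, detection records, pre-filtering, and MOT-format I/O.

Boxes live in pixel units, 0-based, x to the right and y down, stored as
top-left corner plus width/height — the MOT-Challenge interchange convention.
Center/aspect-ratio conversions used by the motion model live in
:mod:`earcount.kalman`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "BoundingBox",
    "Detection",
    "MotParseError",
    "iou",
    "filter_confidence",
    "nms",
    "read_mot_detections",
    "read_mot_groundtruth",
    "write_mot_tracks",
    "read_embedding_sidecar",
    "write_embedding_sidecar",
]

EMBEDDING_NORM_TOL = 1e-6


class MotParseError(ValueError):
    """Raised when a MOT-format line cannot be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: top-left corner (x, y) plus width and height, in pixels."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self):
        for v in (self.x, self.y, self.width, self.height):
            if not np.isfinite(v):
                raise ValueError("box coordinates must be finite")
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"box dimensions must be positive, got {self.width}x{self.height}"
            )

    @property
    def x2(self) -> float:
        return self.x + self.width

    @property
    def y2(self) -> float:
        return self.y + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_tlwh(self) -> np.ndarray:
        return np.array([self.x, self.y, self.width, self.height], dtype=float)


@dataclass
class Detection:
    """One detector output: a frame-stamped box with confidence and an
    optional unit-norm appearance embedding."""

    frame: int
    box: BoundingBox
    confidence: float
    embedding: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if self.frame < 1:
            raise ValueError("frame indices are 1-based")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            norm = float(np.linalg.norm(self.embedding))
            if abs(norm - 1.0) > EMBEDDING_NORM_TOL:
                raise ValueError(
                    f"embedding must be unit-norm within {EMBEDDING_NORM_TOL}, "
                    f"got norm {norm}"
                )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]. Symmetric."""
    ix = max(0.0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def filter_confidence(dets: list[Detection], min_conf: float) -> list[Detection]:
    """Keep detections with confidence >= min_conf (inclusive), preserving order."""
    if not 0.0 <= min_conf <= 1.0:
        raise ValueError("min_conf must lie in [0, 1]")
    return [d for d in dets if d.confidence >= min_conf]


def nms(dets: list[Detection], max_overlap: float) -> list[Detection]:
    """Greedy non-maximum suppression within one frame.

    Detections are visited by descending confidence (ties break toward the
    lower original index); a detection is dropped if its IoU with any
    already-kept detection strictly exceeds ``max_overlap``.
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    kept: list[int] = []
    for i in order:
        if all(iou(dets[i].box, dets[k].box) <= max_overlap for k in kept):
            kept.append(i)
    kept.sort()
    return [dets[i] for i in kept]


# ---------------------------------------------------------------------------
# MOT-Challenge text format
#
# One line per detection: frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z
# id = -1 for raw detections; ground truth carries real ids with conf acting
# as a visibility flag. Fields written with 2 decimal places.
# ---------------------------------------------------------------------------


def _parse_mot_line(line: str, lineno: int) -> tuple[int, int, BoundingBox, float]:
    parts = line.split(",")
    if len(parts) < 7:
        raise MotParseError(f"expected >=7 comma-separated fields, got {len(parts)}", lineno)
    try:
        frame = int(float(parts[0]))
        obj_id = int(float(parts[1]))
        box = BoundingBox(float(parts[2]), float(parts[3]), float(parts[4]), float(parts[5]))
        conf = float(parts[6])
    except (ValueError, OverflowError) as exc:
        raise MotParseError(str(exc), lineno) from None
    return frame, obj_id, box, conf


def read_mot_detections(path) -> dict[int, list[Detection]]:
    """Read raw detections (id column ignored) into a frame -> detections map."""
    frames: dict[int, list[Detection]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            frame, _, box, conf = _parse_mot_line(line, lineno)
            frames.setdefault(frame, []).append(
                Detection(frame=frame, box=box, confidence=min(max(conf, 0.0), 1.0))
            )
    return frames


def read_mot_groundtruth(path) -> dict[int, list[tuple[int, BoundingBox]]]:
    """Read a ground-truth file into frame -> [(object id, box), ...].

    Lines whose conf/visibility column is 0 are skipped.
    """
    frames: dict[int, list[tuple[int, BoundingBox]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            frame, obj_id, box, conf = _parse_mot_line(line, lineno)
            if conf == 0:
                continue
            frames.setdefault(frame, []).append((obj_id, box))
    return frames


def write_mot_tracks(rows, path) -> None:
    """Write (frame, id, box, conf) rows in the 10-column MOT dialect.

    ``rows`` is an iterable of (frame, obj_id, BoundingBox, conf) tuples.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for frame, obj_id, box, conf in rows:
            fh.write(
                f"{frame},{obj_id},{box.x:.2f},{box.y:.2f},"
                f"{box.width:.2f},{box.height:.2f},{conf:.2f},-1,-1,-1\n"
            )


def write_mot_detections(frames: dict[int, list[Detection]], path) -> None:
    """Write raw detections (id = -1) frame by frame in ascending order."""
    rows = (
        (f, -1, d.box, d.confidence)
        for f in sorted(frames)
        for d in frames[f]
    )
    write_mot_tracks(rows, path)


def write_embedding_sidecar(frames: dict[int, list[Detection]], path) -> None:
    """One whitespace-separated row per detection line, in file order."""
    with open(path, "w", encoding="utf-8") as fh:
        for f in sorted(frames):
            for d in frames[f]:
                if d.embedding is None:
                    raise ValueError(f"detection in frame {f} has no embedding")
                fh.write(" ".join(f"{v:.8f}" for v in d.embedding) + "\n")


def read_embedding_sidecar(frames: dict[int, list[Detection]], path) -> dict[int, list[Detection]]:
    """Attach sidecar embeddings to detections read from the matching file.

    Rows pair with detection lines in file order; vectors are re-normalized to
    absorb the sidecar's limited precision.
    """
    vectors = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                v = np.array(line.split(), dtype=float)
                vectors.append(v / np.linalg.norm(v))
    n_dets = sum(len(v) for v in frames.values())
    if len(vectors) != n_dets:
        raise ValueError(
            f"sidecar has {len(vectors)} rows but detection file has {n_dets} lines"
        )
    it = iter(vectors)
    for f in sorted(frames):
        for d in frames[f]:
            d.embedding = next(it)
    return frames
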
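"""Synthetic low-altitude survey scenes for end-to-end tracker testing.

The generator emulates what a downward-looking camera moving at constant
speed over a field of stationary, densely packed small targets produces
after per-frame detection: identities drift through the viewport as the
camera advances, occlusion episodes hide them for a few frames, and the
detection stream is corrupted with misses, box jitter, and short-lived
false positives. Appearance embeddings come from a seeded per-identity
embedder, so cluster separation is controllable.

Randomness is split into independent sub-streams (placement, occlusion,
jitter, misses, false positives, confidence) derived from the scene seed,
so toggling one corruption never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .geometry import (
    BoundingBox,
    Detection,
    write_mot_detections,
    write_embedding_sidecar,
    write_mot_tracks,
)
from .reid import SyntheticEmbedder

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "corrupt_to_detections",
    "write_benchmark",
]

# sub-stream tags for seed splitting
_PLACEMENT, _OCCLUSION, _JITTER, _MISS, _FALSE_POS, _CONF = range(6)


@dataclass
class SceneConfig:
    """Scene and corruption parameters. Defaults describe a constant-speed
    survey pass: a 640 x 640 viewport advancing 6 px/frame over a field of
    ~40 px-tall targets, with mild detector noise."""

    n_identities: int = 80
    n_frames: int = 200
    viewport: tuple[int, int] = (640, 640)      # (width, height) px
    camera_velocity: tuple[float, float] = (6.0, 0.0)   # px/frame
    field_extent: Optional[tuple[float, float]] = None  # derived if None
    height_mean: float = 40.0
    height_std: float = 5.0
    aspect_mean: float = 0.6
    aspect_std: float = 0.08
    drift_std: float = 0.05        # per-object world drift, px/frame
    miss_probability: float = 0.05
    false_positive_rate: float = 0.05   # expected FPs per visible object per frame
    jitter_std: float = 2.0        # box center jitter, px
    occlusion_rate: float = 0.01   # episode starts per identity per frame
    occlusion_duration: int = 3    # frames per episode
    embedding_dim: int = 128
    embedding_noise: float = 0.1   # kappa of the synthetic embedder
    seed: int = 0

    def __post_init__(self):
        for name in ("miss_probability", "occlusion_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_identities < 0:
            raise ValueError("n_identities must be >= 0")
        if self.false_positive_rate < 0 or self.jitter_std < 0:
            raise ValueError("rates must be non-negative")

    def resolved_field_extent(self) -> tuple[float, float]:
        """Field large enough that the viewport sweeps it exactly once."""
        if self.field_extent is not None:
            return self.field_extent
        vx, vy = self.camera_velocity
        w, h = self.viewport
        return (w + abs(vx) * self.n_frames, h + abs(vy) * self.n_frames)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SceneTruth:
    """Ground truth: per-identity viewport-coordinate trajectories.

    ``trajectories[identity]`` maps frame (1-based) to a box for every frame
    the identity is inside the viewport; ``visibility[identity][frame]`` is
    False during occlusion episodes (the box is still recorded).
    """

    config: SceneConfig
    trajectories: dict[int, dict[int, BoundingBox]]
    visibility: dict[int, dict[int, bool]]

    @property
    def total_identities(self) -> int:
        """Distinct identities that ever enter the viewport — the count the
        tracker should recover."""
        return sum(1 for traj in self.trajectories.values() if traj)

    def frame_boxes(self, frame: int, visible_only: bool = True):
        """[(identity, box)] for one frame."""
        out = []
        for ident, traj in self.trajectories.items():
            if frame in traj and (not visible_only or self.visibility[ident][frame]):
                out.append((ident, traj[frame]))
        return out


def generate_scene(config: SceneConfig) -> SceneTruth:
    """Place identities in the world field and project them through the
    moving viewport.

    Every identity is placed so that it is fully inside the viewport for at
    least a handful of frames (a target that never plausibly enters view is
    not a countable object). A box is recorded for a frame when it lies
    fully inside the viewport; occlusion episodes flip its visibility flag.
    """
    rng_place = config.rng(_PLACEMENT)
    rng_occl = config.rng(_OCCLUSION)
    vx, vy = config.camera_velocity
    vw, vh = config.viewport
    fw, fh = config.resolved_field_extent()

    trajectories: dict[int, dict[int, BoundingBox]] = {}
    visibility: dict[int, dict[int, bool]] = {}
    min_window = 10  # frames of guaranteed full visibility
    for ident in range(config.n_identities):
        h = max(4.0, rng_place.normal(config.height_mean, config.height_std))
        w = max(2.0, rng_place.normal(config.aspect_mean, config.aspect_std) * h)
        # world-x band in which the box stays fully visible for at least
        # min_window frames before exiting (lo) and enters early enough (hi)
        x_lo = abs(vx) * min_window
        x_hi = vw - w + abs(vx) * max(0, config.n_frames - min_window)
        x = rng_place.uniform(x_lo, max(x_lo + 1.0, x_hi))
        y = rng_place.uniform(0.0, max(1.0, min(fh, vh) - h))
        drift = rng_place.normal(0.0, config.drift_std, size=2)

        traj: dict[int, BoundingBox] = {}
        vis: dict[int, bool] = {}
        occluded_until = 0
        for t in range(1, config.n_frames + 1):
            cam_x, cam_y = vx * (t - 1), vy * (t - 1)
            bx = x + drift[0] * (t - 1) - cam_x
            by = y + drift[1] * (t - 1) - cam_y
            if bx < 0 or by < 0 or bx + w > vw or by + h > vh:
                continue
            traj[t] = BoundingBox(bx, by, w, h)
            if t <= occluded_until:
                vis[t] = False
            elif rng_occl.random() < config.occlusion_rate:
                occluded_until = t + config.occlusion_duration - 1
                vis[t] = False
            else:
                vis[t] = True
        trajectories[ident] = traj
        visibility[ident] = vis
    return SceneTruth(config=config, trajectories=trajectories, visibility=visibility)


def corrupt_to_detections(
    truth: SceneTruth,
    config: Optional[SceneConfig] = None,
    embedder: Optional[SyntheticEmbedder] = None,
) -> dict[int, list[Detection]]:
    """Turn ground truth into a detector-like stream.

    Visible boxes are emitted with seeded center/size jitter and a
    confidence in [0.55, 1]; each is dropped independently with the miss
    probability. False positives arrive per frame as a Poisson count with
    mean ``false_positive_rate * n_visible``; each lives a single frame and
    carries a fresh random identity's embedding, so it can never accumulate
    gallery support or survive the confirmation gate.
    """
    cfg = config or truth.config
    embedder = embedder or SyntheticEmbedder(
        dim=cfg.embedding_dim, kappa=cfg.embedding_noise, seed=cfg.seed
    )
    rng_jit = cfg.rng(_JITTER)
    rng_miss = cfg.rng(_MISS)
    rng_fp = cfg.rng(_FALSE_POS)
    rng_conf = cfg.rng(_CONF)
    vw, vh = cfg.viewport
    fp_ident = 1_000_000  # fresh identities for clutter embeddings

    detections: dict[int, list[Detection]] = {}
    for t in range(1, cfg.n_frames + 1):
        dets: list[Detection] = []
        visible = truth.frame_boxes(t, visible_only=True)
        for ident, box in visible:
            if rng_miss.random() < cfg.miss_probability:
                continue
            dx, dy = rng_jit.normal(0.0, cfg.jitter_std, size=2)
            dw, dh = rng_jit.normal(0.0, cfg.jitter_std / 2.0, size=2)
            jittered = BoundingBox(
                box.x + dx, box.y + dy,
                max(2.0, box.width + dw), max(2.0, box.height + dh),
            )
            dets.append(Detection(
                frame=t,
                box=jittered,
                confidence=float(rng_conf.uniform(0.55, 1.0)),
                embedding=embedder.draw(ident, draw_index=t),
            ))
        n_fp = rng_fp.poisson(cfg.false_positive_rate * len(visible))
        for _ in range(n_fp):
            h = max(4.0, rng_fp.normal(cfg.height_mean, cfg.height_std))
            w = max(2.0, rng_fp.normal(cfg.aspect_mean, cfg.aspect_std) * h)
            x = rng_fp.uniform(0.0, max(1.0, vw - w))
            y = rng_fp.uniform(0.0, max(1.0, vh - h))
            dets.append(Detection(
                frame=t,
                box=BoundingBox(x, y, w, h),
                confidence=float(rng_conf.uniform(0.3, 0.9)),
                embedding=embedder.draw(fp_ident, draw_index=t),
            ))
            fp_ident += 1
        detections[t] = dets
    return detections


def write_benchmark(truth: SceneTruth, detections: dict[int, list[Detection]],
                    out_dir) -> None:
    """Write gt.txt, det.txt, det.emb, and truth_count.json into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt_rows = []
    for t in range(1, truth.config.n_frames + 1):
        for ident, box in truth.frame_boxes(t, visible_only=False):
            # conf column doubles as the visibility flag in ground truth
            gt_rows.append((t, ident + 1, box, float(truth.visibility[ident][t])))
    write_mot_tracks(gt_rows, out / "gt.txt")
    write_mot_detections(detections, out / "det.txt")
    if any(d.embedding is not None for dets in detections.values() for d in dets):
        write_embedding_sidecar(detections, out / "det.emb")
    with open(out / "truth_count.json", "w", encoding="utf-8") as fh:
        json.dump({"true_count": truth.total_identities}, fh)
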
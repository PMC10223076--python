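"""Synthetic survey-scene generator and end-to-end tracker recovery."""

import json

import numpy as np
import pytest

from earcount import (
    SceneConfig,
    count_report,
    corrupt_to_detections,
    generate_scene,
    read_mot_detections,
    read_mot_groundtruth,
    run_tracker,
    write_benchmark,
)


def clean(**kw):
    base = dict(miss_probability=0.0, false_positive_rate=0.0, jitter_std=0.0,
                occlusion_rate=0.0, embedding_noise=0.0)
    base.update(kw)
    return SceneConfig(**base)


class TestGenerateScene:
    def test_static_camera_static_boxes(self):
        cfg = clean(n_identities=1, n_frames=20, camera_velocity=(0.0, 0.0),
                    drift_std=0.0, seed=1)
        truth = generate_scene(cfg)
        traj = truth.trajectories[0]
        assert len(traj) == 20
        first = traj[1].as_tlwh()
        for t in traj:
            assert traj[t].as_tlwh() == pytest.approx(first)

    def test_camera_motion_shifts_viewport_coordinates(self):
        cfg = clean(n_identities=3, n_frames=10, camera_velocity=(5.0, 0.0),
                    drift_std=0.0, seed=2)
        truth = generate_scene(cfg)
        for traj in truth.trajectories.values():
            frames = sorted(traj)
            for a, b in zip(frames, frames[1:]):
                if b == a + 1:
                    assert traj[b].x - traj[a].x == pytest.approx(-5.0)

    def test_same_seed_reproducible(self):
        cfg = SceneConfig(n_identities=10, n_frames=30, seed=5)
        t1, t2 = generate_scene(cfg), generate_scene(cfg)
        assert t1.trajectories.keys() == t2.trajectories.keys()
        for i in t1.trajectories:
            assert t1.trajectories[i].keys() == t2.trajectories[i].keys()
            for f in t1.trajectories[i]:
                assert np.array_equal(t1.trajectories[i][f].as_tlwh(),
                                      t2.trajectories[i][f].as_tlwh())
            assert t1.visibility[i] == t2.visibility[i]

    def test_empty_scene_allowed(self):
        truth = generate_scene(clean(n_identities=0, n_frames=5))
        assert truth.total_identities == 0


class TestCorruption:
    def test_no_corruption_detections_equal_truth(self):
        cfg = clean(n_identities=5, n_frames=30, seed=3)
        truth = generate_scene(cfg)
        dets = corrupt_to_detections(truth)
        for t in range(1, 31):
            gt = truth.frame_boxes(t)
            assert len(dets[t]) == len(gt)
            got = np.array(sorted(d.box.as_tlwh().tolist() for d in dets[t]))
            want = np.array(sorted(b.as_tlwh().tolist() for _, b in gt))
            assert got == pytest.approx(want)

    def test_total_miss_drops_everything(self):
        cfg = clean(n_identities=5, n_frames=10, miss_probability=1.0, seed=4)
        truth = generate_scene(cfg)
        dets = corrupt_to_detections(truth)
        assert all(len(v) == 0 for v in dets.values())

    def test_miss_fraction_binomial(self):
        cfg = clean(n_identities=40, n_frames=60, miss_probability=0.1, seed=6)
        truth = generate_scene(cfg)
        dets = corrupt_to_detections(truth)
        n_true = sum(len(truth.frame_boxes(t)) for t in range(1, 61))
        n_det = sum(len(v) for v in dets.values())
        dropped = (n_true - n_det) / n_true
        sigma = np.sqrt(0.1 * 0.9 / n_true)
        assert abs(dropped - 0.1) < 3 * sigma

    def test_toggling_jitter_does_not_perturb_misses(self):
        base = clean(n_identities=20, n_frames=40, miss_probability=0.2, seed=8)
        jittered = clean(n_identities=20, n_frames=40, miss_probability=0.2,
                         jitter_std=3.0, seed=8)
        d1 = corrupt_to_detections(generate_scene(base))
        d2 = corrupt_to_detections(generate_scene(jittered))
        assert all(len(d1[t]) == len(d2[t]) for t in d1)


class TestWriteBenchmark:
    def test_round_trip_and_count(self, tmp_path):
        cfg = SceneConfig(n_identities=8, n_frames=25, seed=9)
        truth = generate_scene(cfg)
        dets = corrupt_to_detections(truth)
        write_benchmark(truth, dets, tmp_path)
        gt = read_mot_groundtruth(tmp_path / "gt.txt")
        ids = {i for rows in gt.values() for i, _ in rows}
        with open(tmp_path / "truth_count.json") as fh:
            assert json.load(fh)["true_count"] == truth.total_identities
        assert len(ids) <= truth.total_identities  # occluded-only frames skipped
        back = read_mot_detections(tmp_path / "det.txt")
        assert sum(len(v) for v in back.values()) == sum(len(v) for v in dets.values())
        # boxes survive to 2 decimal places
        for t, rows in gt.items():
            for ident, box in rows:
                orig = truth.trajectories[ident - 1][t]
                assert box.as_tlwh() == pytest.approx(orig.as_tlwh(), abs=0.005)

    def test_empty_scene_files(self, tmp_path):
        truth = generate_scene(clean(n_identities=0, n_frames=3))
        write_benchmark(truth, corrupt_to_detections(truth), tmp_path)
        with open(tmp_path / "truth_count.json") as fh:
            assert json.load(fh)["true_count"] == 0
        assert read_mot_detections(tmp_path / "det.txt") == {}


class TestEndToEndRecovery:
    def test_zero_corruption_exact_count(self):
        # with perfect detections and embeddings the tracker recovers the
        # identity count exactly
        for seed in range(6):
            cfg = clean(n_identities=12, n_frames=80, seed=seed)
            truth = generate_scene(cfg)
            history, tracker = run_tracker(corrupt_to_detections(truth))
            assert len(tracker.confirmed_ids) == truth.total_identities

    def test_counting_error_non_decreasing_in_miss_rate(self):
        # averaged over seeds, higher miss probability never improves the count
        mean_err = []
        for miss in (0.0, 0.1, 0.3):
            errs = []
            for seed in range(4):
                cfg = SceneConfig(n_identities=25, n_frames=100,
                                  miss_probability=miss, false_positive_rate=0.0,
                                  jitter_std=0.0, occlusion_rate=0.0, seed=seed)
                truth = generate_scene(cfg)
                _, tracker = run_tracker(corrupt_to_detections(truth))
                rep = count_report(len(tracker.confirmed_ids), truth.total_identities)
                errs.append(rep.l1_loss)
            mean_err.append(np.mean(errs))
        assert mean_err[0] <= mean_err[1] + 1e-9
        assert mean_err[1] <= mean_err[2] + 1e-9
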
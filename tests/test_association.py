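"""Gallery distance, gating, combined cost, Hungarian assignment, cascade."""

import numpy as np
import pytest

from earcount import (
    CHI2_GATE_4DOF,
    BoundingBox,
    CostMatrix,
    EmptyGalleryError,
    Gallery,
    appearance_gate,
    combined_cost,
    cosine_gallery_distance,
    iou_match,
    matching_cascade,
    motion_gate,
    solve_assignment,
)
from oracles import brute_force_min_cost


class TestGallery:
    def test_self_similarity_zero(self):
        g = Gallery()
        v = np.zeros(8)
        v[0] = 1.0
        g.add(v)
        assert cosine_gallery_distance(g, v) == pytest.approx(0.0)

    def test_orthogonal_vector_distance_one(self):
        g = Gallery()
        g.add(np.eye(8)[0])
        assert cosine_gallery_distance(g, np.eye(8)[1]) == pytest.approx(1.0)

    def test_min_over_gallery(self):
        # gallery members with cosine similarity 0.5 and 0.9 to the query
        q = np.array([1.0, 0.0])
        g = Gallery()
        for sim in (0.5, 0.9):
            g.add(np.array([sim, np.sqrt(1 - sim**2)]))
        assert cosine_gallery_distance(g, q) == pytest.approx(0.1)

    def test_empty_gallery_signals(self):
        with pytest.raises(EmptyGalleryError):
            cosine_gallery_distance(Gallery(), np.array([1.0, 0.0]))

    def test_capacity_bound_and_normalization(self):
        g = Gallery(capacity=3)
        for i in range(5):
            g.add(np.full(4, i + 1.0))  # non-unit vectors, normalized at insert
        assert len(g) == 3
        assert np.allclose(np.linalg.norm(g.as_matrix(), axis=1), 1.0)

    def test_distance_monotone_in_gallery_growth(self):
        rng = np.random.default_rng(5)
        q = rng.standard_normal(16)
        q /= np.linalg.norm(q)
        g = Gallery()
        prev = None
        for _ in range(20):
            g.add(rng.standard_normal(16))
            d = cosine_gallery_distance(g, q)
            if prev is not None:
                assert d <= prev + 1e-12
            prev = d


class TestGates:
    def test_zero_distance_always_admissible(self):
        assert motion_gate(0.0, 1e-9 + 1e-12)

    def test_gate_boundary_is_inclusive(self):
        assert motion_gate(CHI2_GATE_4DOF, CHI2_GATE_4DOF)
        assert appearance_gate(0.3, 0.3)

    def test_chi_square_quantile_excludes(self):
        # 9.5 exceeds the chi-square(4) 0.95 quantile 9.4877
        assert CHI2_GATE_4DOF == pytest.approx(9.4877, abs=1e-4)
        assert not motion_gate(9.5, CHI2_GATE_4DOF)


class TestCombinedCost:
    @pytest.mark.parametrize("lam,d1,d2,expected", [
        (1.0, 3.7, 0.9, 3.7),
        (0.0, 3.7, 0.9, 0.9),
        (0.5, 2.0, 0.4, 1.2),
    ])
    def test_convex_combination(self, lam, d1, d2, expected):
        assert combined_cost(d1, d2, lam) == pytest.approx(expected)

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            combined_cost(1.0, 1.0, 1.5)


class TestSolveAssignment:
    def test_single_admissible_pair(self):
        res = solve_assignment(CostMatrix([[0.4]], [[True]]))
        assert res.matches == [(0, 0)]

    def test_two_by_two(self):
        res = solve_assignment(CostMatrix([[1, 2], [2, 1]], np.ones((2, 2), bool)))
        assert res.matches == [(0, 0), (1, 1)]

    def test_all_gated_out(self):
        res = solve_assignment(CostMatrix([[1, 2], [2, 1]], np.zeros((2, 2), bool)))
        assert res.matches == []
        assert res.unmatched_tracks == [0, 1]
        assert res.unmatched_detections == [0, 1]

    def test_empty_inputs(self):
        res = solve_assignment(CostMatrix(np.zeros((0, 3)), np.zeros((0, 3), bool)))
        assert res.matches == [] and res.unmatched_detections == [0, 1, 2]

    def test_matches_brute_force_on_random_gated_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n_t, n_d = rng.integers(1, 6, size=2)
            values = rng.uniform(0, 10, (n_t, n_d))
            mask = rng.random((n_t, n_d)) < 0.7
            res = solve_assignment(CostMatrix(values, mask))
            got = sum(values[t, d] for t, d in res.matches)
            assert got == pytest.approx(brute_force_min_cost(values, mask))
            for t, d in res.matches:  # gated pairs never matched
                assert mask[t, d]

    def test_partition_covers_inputs_once(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 1, (4, 6))
        res = solve_assignment(CostMatrix(values, values < 0.8))
        tracks = [t for t, _ in res.matches] + res.unmatched_tracks
        dets = [d for _, d in res.matches] + res.unmatched_detections
        assert sorted(tracks) == list(range(4))
        assert sorted(dets) == list(range(6))


class TestMatchingCascade:
    @staticmethod
    def _cost_fn_from(values, mask):
        def cost_fn(track_idx, det_idx):
            return CostMatrix(values[np.ix_(track_idx, det_idx)],
                              mask[np.ix_(track_idx, det_idx)])
        return cost_fn

    def test_uniform_age_equals_global_assignment(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 5, (4, 4))
        mask = np.ones((4, 4), bool)
        cascade = matching_cascade(self._cost_fn_from(values, mask),
                                   [1, 1, 1, 1], 4, max_age_levels=10)
        direct = solve_assignment(CostMatrix(values, mask))
        assert cascade.matches == direct.matches

    def test_recently_updated_track_wins_contested_detection(self):
        values = np.array([[1.0], [1.0]])
        mask = np.ones((2, 1), bool)
        # track 0 fresh (age 1), track 1 stale (age 6): equal cost, 0 wins
        res = matching_cascade(self._cost_fn_from(values, mask),
                               [1, 6], 1, max_age_levels=10)
        assert res.matches == [(0, 0)]
        assert res.unmatched_tracks == [1]

    def test_no_detections(self):
        res = matching_cascade(lambda t, d: CostMatrix(np.zeros((len(t), 0)),
                                                       np.zeros((len(t), 0), bool)),
                               [1, 2, 3], 0, max_age_levels=5)
        assert res.matches == []
        assert res.unmatched_tracks == [0, 1, 2]


class TestIouMatch:
    def test_perfect_overlap_matches_at_zero_cost(self):
        box = BoundingBox(0, 0, 10, 10)
        res = iou_match([box], [box], 0.8)
        assert res.matches == [(0, 0)]

    def test_disjoint_boxes_unmatched(self):
        res = iou_match([BoundingBox(0, 0, 5, 5)], [BoundingBox(50, 50, 5, 5)], 0.8)
        assert res.matches == []

    def test_crossed_overlaps_minimize_total_cost(self):
        # two tracks, two detections with crossing overlap structure
        t0, t1 = BoundingBox(0, 0, 10, 10), BoundingBox(8, 0, 10, 10)
        d0, d1 = BoundingBox(1, 0, 10, 10), BoundingBox(7, 0, 10, 10)
        res = iou_match([t0, t1], [d0, d1], max_iou_distance=1.0)
        from earcount import iou
        got_cost = sum(1 - iou([t0, t1][t], [d0, d1][d]) for t, d in res.matches)
        want_cost = min(
            sum(1 - iou([t0, t1][t], [d0, d1][d]) for t, d in pairs)
            for pairs in ([(0, 0), (1, 1)], [(0, 1), (1, 0)])
        )
        assert got_cost == pytest.approx(want_cost)
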
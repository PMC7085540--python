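"""Trackers: assignment costs, Hungarian optimality, state filtering,
appearance matching, and identity maintenance on synthetic streams."""

import itertools
import math

import numpy as np
import pytest

from activetrack import (BoundingBox, Detection, FrameDetections,
                         HungarianTracker, KinematicState, PipelineConfig,
                         Track, appearance_distance, assign_hungarian,
                         deepsort_cost, default_embedder, hungarian_cost,
                         mahalanobis_distance, track_sequence)
from activetrack.tracking import (INFEASIBLE, initiate_state, predict_state,
                                  update_state)


def box_centered(cx, cy, w=10, h=10):
    return BoundingBox(cx - w / 2, cy - h / 2, w, h)


def track_at(tid, cx, cy, w=10, h=10, frame=0):
    return Track(id=tid, assignments=[(frame, box_centered(cx, cy, w, h))])


class TestHungarianCost:
    def test_blended_arithmetic(self):
        # centroids 5 px apart (3-4-5), areas 100 vs 110, w=0.5
        track = track_at(1, 10, 10, 10, 10)
        det = Detection(1, box_centered(13, 14, 11, 10))
        assert hungarian_cost(track, det, w=0.5) == pytest.approx(
            0.5 * 5 + 0.5 * 10)

    def test_identical_box_costs_zero(self):
        track = track_at(1, 20, 20)
        det = Detection(1, box_centered(20, 20))
        assert hungarian_cost(track, det) == 0.0

    def test_gate_makes_far_pair_infeasible(self):
        track = track_at(1, 0, 0)
        det = Detection(1, box_centered(120, 0))
        assert hungarian_cost(track, det, T=100.0) == INFEASIBLE
        # strictly inside the gate is feasible
        near = Detection(1, box_centered(99, 0))
        assert math.isfinite(hungarian_cost(track, near, T=100.0))

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            hungarian_cost(Track(id=1), Detection(0, box_centered(0, 0)))


def oracle_assignment(cost):
    """Exhaustive-permutation oracle on the infeasibility-padded matrix.

    Returns the minimum achievable (n_matched, -total_cost) ordering, i.e.
    maximum-cardinality feasible matching with minimal cost among those.
    """
    n_t, n_d = cost.shape
    best = None
    if n_t <= n_d:
        candidates = (list(zip(range(n_t), cols))
                      for cols in itertools.permutations(range(n_d), n_t))
    else:
        candidates = (list(zip(rows, range(n_d)))
                      for rows in itertools.permutations(range(n_t), n_d))
    for pairs in candidates:
        feasible = [(r, c) for r, c in pairs if np.isfinite(cost[r, c])]
        key = (-len(feasible), sum(cost[r, c] for r, c in feasible))
        if best is None or key < best[0]:
            best = (key, feasible)
    return best


class TestAssignHungarian:
    def test_no_tracks(self):
        cfg = PipelineConfig()
        dets = FrameDetections(0, [Detection(0, box_centered(5, 5)),
                                   Detection(0, box_centered(30, 5))])
        result = assign_hungarian([], dets, cfg)
        assert result.matches == []
        assert result.unmatched_detections == [0, 1]

    def test_nearest_neighbour_beats_crossing(self):
        cfg = PipelineConfig(w=1.0)
        tracks = [track_at(1, 0, 0), track_at(2, 10, 0)]
        dets = FrameDetections(1, [Detection(1, box_centered(1, 0)),
                                   Detection(1, box_centered(9, 0))])
        result = assign_hungarian(tracks, dets, cfg)
        assert sorted(result.matches) == [(1, 0), (2, 1)]

    def test_matches_permutation_oracle(self):
        cfg = PipelineConfig(w=0.7, T=60.0)
        rng = np.random.default_rng(123)
        for _ in range(200):
            n_t = int(rng.integers(2, 7))
            n_d = int(rng.integers(2, 7))
            tracks = [track_at(i + 1, *rng.uniform(0, 100, 2),
                               *rng.uniform(5, 20, 2)) for i in range(n_t)]
            dets = FrameDetections(1, [
                Detection(1, box_centered(*rng.uniform(0, 100, 2),
                                          *rng.uniform(5, 20, 2)))
                for _ in range(n_d)])
            cost = np.array([[hungarian_cost(t, d, cfg.w, cfg.T)
                              for d in dets] for t in tracks])
            result = assign_hungarian(tracks, dets, cfg)
            got_cost = sum(cost[tid - 1, j] for tid, j in result.matches)
            (neg_k, best_cost), _ = oracle_assignment(cost)
            assert len(result.matches) == -neg_k
            assert got_cost == pytest.approx(best_cost)

    def test_one_to_one_invariant(self):
        cfg = PipelineConfig()
        rng = np.random.default_rng(4)
        tracks = [track_at(i + 1, *rng.uniform(0, 60, 2)) for i in range(4)]
        dets = FrameDetections(1, [
            Detection(1, box_centered(*rng.uniform(0, 60, 2)))
            for _ in range(6)])
        r = assign_hungarian(tracks, dets, cfg)
        tids = [t for t, _ in r.matches] + r.unmatched_tracks
        dids = [d for _, d in r.matches] + r.unmatched_detections
        assert sorted(tids) == [1, 2, 3, 4]
        assert sorted(dids) == list(range(6))


class TestTrackerLifecycle:
    def test_termination_after_patience_exceeded(self):
        cfg = PipelineConfig(M=20)
        tracker = HungarianTracker(cfg)
        tracker.step(FrameDetections(0, [Detection(0, box_centered(10, 10))]))
        for f in range(1, 21):       # 20 consecutive misses: still open
            tracker.step(FrameDetections(f))
        assert len(tracker.active) == 1
        tracker.step(FrameDetections(21))   # 21st miss closes it
        assert tracker.active == []
        assert len(tracker.finished) == 1

    def test_every_detection_matched_spawns_nothing(self):
        cfg = PipelineConfig()
        tracker = HungarianTracker(cfg)
        tracker.step(FrameDetections(0, [Detection(0, box_centered(10, 10)),
                                         Detection(0, box_centered(50, 10))]))
        tracker.step(FrameDetections(1, [Detection(1, box_centered(11, 10)),
                                         Detection(1, box_centered(49, 10))]))
        assert len(tracker.tracks) == 2

    def test_gap_resume_keeps_identity(self):
        cfg = PipelineConfig(M=20)
        tracker = HungarianTracker(cfg)
        tracker.step(FrameDetections(0, [Detection(0, box_centered(10, 10))]))
        for f in range(1, 6):        # 5-frame detector dropout
            tracker.step(FrameDetections(f))
        tracker.step(FrameDetections(6, [Detection(6, box_centered(14, 10))]))
        assert len(tracker.tracks) == 1
        t = tracker.tracks[0]
        assert t.frames == [0, 6]
        assert t.misses == 0

    def test_out_of_order_frames_rejected(self):
        tracker = HungarianTracker(PipelineConfig())
        tracker.step(FrameDetections(3))
        with pytest.raises(ValueError):
            tracker.step(FrameDetections(3))

    def test_ids_unique_and_never_reused(self):
        cfg = PipelineConfig(T=5.0)   # tight gate: every far det is new
        tracker = HungarianTracker(cfg)
        rng = np.random.default_rng(2)
        seen = []
        for f in range(15):
            dets = [Detection(f, box_centered(*rng.uniform(0, 200, 2)))
                    for _ in range(rng.integers(0, 4))]
            tracker.step(FrameDetections(f, dets))
            ids = [t.id for t in tracker.tracks]
            assert len(ids) == len(set(ids))
            seen.append(set(ids))
        for a, b in zip(seen, seen[1:]):
            assert a <= b                      # closed ids never recycled


class TestKinematics:
    def test_mahalanobis_zero_at_prediction(self):
        state = KinematicState(np.array([10.0, 20.0, 0.5, 40.0]), np.eye(4))
        det = Detection(0, BoundingBox(0, 0, 20, 40))
        assert mahalanobis_distance(state, det) == pytest.approx(0.0)

    def test_mahalanobis_quadratic_form(self):
        # S = 4I, offset (2,0,0,0): (2^2)/4 = 1
        state = KinematicState(np.array([10.0, 20.0, 0.5, 40.0]),
                               4.0 * np.eye(4))
        det = Detection(0, BoundingBox(2, 0, 20, 40))  # cx 12 -> offset 2
        assert mahalanobis_distance(state, det) == pytest.approx(1.0)

    def test_covariance_scaling_inverse(self):
        rng = np.random.default_rng(3)
        mean = np.array([50.0, 40.0, 0.6, 30.0])
        A = rng.normal(size=(4, 4))
        cov = A @ A.T + 4 * np.eye(4)
        det = Detection(0, box_centered(55, 44, 18, 30))
        d = mahalanobis_distance(KinematicState(mean, cov), det)
        d_scaled = mahalanobis_distance(KinematicState(mean, 2 * cov), det)
        assert d_scaled == pytest.approx(d / 2)

    def test_filter_converges_on_constant_velocity(self):
        state = initiate_state(box_centered(10, 50, 10, 20))
        for f in range(1, 12):
            state = predict_state(state)
            state = update_state(state, box_centered(10 + 3 * f, 50, 10, 20))
        state = predict_state(state)
        y, _ = state.projected()
        assert y[0] == pytest.approx(10 + 3 * 12, abs=0.5)


class TestAppearance:
    def test_gallery_contains_query(self):
        r = np.zeros(4)
        r[0] = 1.0
        assert appearance_distance([r], r) == pytest.approx(0.0)

    def test_orthogonal_descriptor(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert appearance_distance([a], b) == pytest.approx(1.0)

    def test_min_over_gallery(self):
        gallery = [np.array([1.0, 0.0]), np.array([0.6, 0.8])]
        r = np.array([0.8, 0.6])
        assert appearance_distance(gallery, r) == pytest.approx(0.04)

    def test_empty_gallery_rejected(self):
        with pytest.raises(ValueError):
            appearance_distance([], np.array([1.0, 0.0]))

    def test_embedder_unit_norm_and_determinism(self):
        rng = np.random.default_rng(8)
        frame = rng.uniform(size=(60, 80))
        for _ in range(100):
            box = BoundingBox(*rng.uniform(0, 50, 2), *rng.uniform(4, 20, 2))
            d = default_embedder(frame, box)
            assert d.shape == (128,)
            assert np.linalg.norm(d) == pytest.approx(1.0)
            assert np.array_equal(d, default_embedder(frame, box))

    def test_disjoint_intensity_ranges_near_orthogonal(self):
        rng = np.random.default_rng(9)
        frame = np.zeros((40, 80))
        frame[10:30, 5:25] = rng.uniform(0.0, 0.15, (20, 20))
        frame[10:30, 45:65] = rng.uniform(0.85, 1.0, (20, 20))
        d_dark = default_embedder(frame, BoundingBox(5, 10, 20, 20))
        d_bright = default_embedder(frame, BoundingBox(45, 10, 20, 20))
        assert appearance_distance([d_dark], d_bright) > 0.9

    def test_gallery_bounded_oldest_evicted(self, small_scene):
        _, frames, truth = small_scene
        cfg = PipelineConfig(tracker="deepsort", gallery_size=10)
        tracks = track_sequence(truth.detections(), cfg, frames)
        for t in tracks:
            assert len(t.gallery) <= 10


class TestDeepSortCost:
    def _track(self):
        t = track_at(1, 20, 20, 10, 20)
        t.state = initiate_state(t.last_box)
        t.gallery = [np.array([1.0, 0.0])]
        return t

    def test_lambda_limits(self):
        t = self._track()
        det = Detection(1, box_centered(21, 20, 10, 20))
        r = np.array([0.8, 0.6])
        d1 = mahalanobis_distance(t.state, det)
        d2 = appearance_distance(t.gallery, r)
        gates = dict(mahalanobis_gate=1e9, appearance_gate=1.0)
        assert deepsort_cost(t, det, r, lam=1.0, **gates) == pytest.approx(d1)
        assert deepsort_cost(t, det, r, lam=0.0, **gates) == pytest.approx(d2)
        assert deepsort_cost(t, det, r, lam=0.5, **gates) == pytest.approx(
            0.5 * d1 + 0.5 * d2)

    def test_gate_violation_infeasible(self):
        t = self._track()
        det = Detection(1, box_centered(21, 20, 10, 20))
        r = np.array([0.0, 1.0])     # appearance distance 1 > gate 0.2
        assert deepsort_cost(t, det, r) == INFEASIBLE


class TestIdentityMaintenance:
    @pytest.mark.parametrize("backend", ["hungarian", "deepsort"])
    def test_clean_stream_exact_recovery(self, backend, small_scene):
        """No jitter, no dropout: one track per sprite, zero switches."""
        _, frames, truth = small_scene
        cfg = PipelineConfig(tracker=backend)
        tracks = track_sequence(truth.detections(), cfg, frames)
        assert len(tracks) == len(truth.boxes)
        gt = {tuple(t.assignments) for t in truth.gt_tracks().values()}
        assert {tuple(t.assignments) for t in tracks} == gt

    def test_occlusion_reid_where_distance_is_ambiguous(self):
        """Two subjects swap sides during a 10-frame occlusion. The nearest-
        centroid cost links each to the other's old position; the appearance
        gallery re-identifies them correctly."""
        rng = np.random.default_rng(3)
        bg = rng.uniform(0.45, 0.55, (60, 120))
        tex_a = rng.uniform(0.00, 0.22, (14, 12))
        tex_b = rng.uniform(0.78, 1.00, (14, 12))
        pos_a = {f: (30, 20) for f in range(5)}
        pos_b = {f: (58, 20) for f in range(5)}
        for f in range(15, 25):      # reappear crossed after frames 5..14
            pos_a[f] = (52, 20)
            pos_b[f] = (36, 20)
        frames, dets = [], []
        for f in range(25):
            img = bg.copy()
            ds = []
            for tex, pos in ((tex_a, pos_a.get(f)), (tex_b, pos_b.get(f))):
                if pos is not None:
                    x, y = pos
                    img[y:y + 14, x:x + 12] = tex
                    ds.append(Detection(f, BoundingBox(x, y, 12, 14)))
            frames.append(img)
            dets.append(FrameDetections(f, ds))

        hung = track_sequence(dets, PipelineConfig(tracker="hungarian"))
        ends_h = {t.assignments[0][1].x: t.assignments[-1][1].x for t in hung}
        assert ends_h == {30: 36, 58: 52}     # identities swapped

        deep = track_sequence(dets, PipelineConfig(tracker="deepsort"), frames)
        assert len(deep) == 2
        ends_d = {t.assignments[0][1].x: t.assignments[-1][1].x for t in deep}
        assert ends_d == {30: 52, 58: 36}     # identities preserved
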
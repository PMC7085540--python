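"""Tracking-by-detection: link per-frame boxes into persistent identities.

Two online backends share one assignment machinery:

* ``HungarianTracker`` — the baseline. The cost of assigning detection i to
  a track is ``w * d(C_prev, C_i) + (1 - w) * |P_i - P_prev|``, a blend of
  the Euclidean centroid displacement (px) and the absolute area change
  (px^2); a pair is infeasible when the centroid distance reaches the gate
  ``T``. The Hungarian method minimises the total cost over feasible
  one-to-one assignments (maximum-cardinality first — an unmatchable pair is
  never preferred over a feasible match).

* ``DeepSortTracker`` — adds a constant-velocity linear-Gaussian filter on
  (cx, cy, aspect, height) and an appearance gallery. The pair cost is
  ``lam * d1 + (1 - lam) * d2`` with d1 the squared Mahalanobis distance of
  the detection from the predicted state and d2 the cosine appearance
  distance ``min_k (1 - r . r_k)`` over the track's most recent descriptors;
  either distance beyond its gate makes the pair infeasible.

Both backends close a track after more than ``M`` consecutive frames
without an assignment and spawn a new track from every unmatched detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import BoundingBox, Detection, FrameDetections, Track, centroid_distance
from .io import PipelineConfig, logger

#: Marker for an unassignable track/detection pair.
INFEASIBLE = math.inf

# Finite stand-in for INFEASIBLE inside the solver; must dwarf any feasible
# total so that the solver prefers any feasible match over an infeasible one.
_BIG = 1e12


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    """One frame's assignment: matched pairs and the leftovers on each side."""

    matches: list[tuple[int, int]]           # (track id, detection index)
    unmatched_tracks: list[int]
    unmatched_detections: list[int]


def hungarian_cost(track: Track, det: Detection, w: float = 0.5,
                   T: float = 100.0, distance_scale: float = 1.0,
                   area_scale: float = 1.0) -> float:
    """Blended centroid-distance / area-difference cost of a (track, det) pair.

    Returns ``INFEASIBLE`` when the centroid distance is not below the gate
    ``T`` (such a box can never be assigned to the track, even if nearest).
    """
    if not track.assignments:
        raise ValueError("cost of an empty track is undefined")
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"w must lie in [0,1], got {w}")
    prev = track.last_box
    d = centroid_distance(prev, det.box)
    if d >= T:
        return INFEASIBLE
    return (w * distance_scale * d
            + (1.0 - w) * area_scale * abs(det.box.area - prev.area))


def _solve(cost: np.ndarray, track_ids: list[int]) -> AssignmentResult:
    """Minimum-cost maximum-cardinality assignment over a feasibility-masked matrix.

    Ties between equal-cost optima are broken toward the lexicographically
    smallest (row, column) pairing via an epsilon perturbation far below any
    meaningful cost difference.
    """
    n_t, n_d = cost.shape
    if n_t == 0 or n_d == 0:
        return AssignmentResult([], list(track_ids), list(range(n_d)))
    finite = np.where(np.isfinite(cost), cost, _BIG)
    eps = 1e-9 * (1.0 + np.max(finite[finite < _BIG], initial=0.0))
    tie = np.arange(n_t)[:, None] * n_d + np.arange(n_d)[None, :]
    rows, cols = linear_sum_assignment(finite + eps * tie / (n_t * n_d + 1))
    matches, um_t, um_d = [], set(range(n_t)), set(range(n_d))
    for r, c in zip(rows, cols):
        if np.isfinite(cost[r, c]):
            matches.append((track_ids[r], c))
            um_t.discard(r)
            um_d.discard(c)
    return AssignmentResult(matches,
                            [track_ids[r] for r in sorted(um_t)],
                            sorted(um_d))


def assign_hungarian(tracks: list[Track], dets: FrameDetections,
                     cfg: PipelineConfig) -> AssignmentResult:
    """Assign one frame's detections to tracks by the baseline blended cost."""
    cost = np.full((len(tracks), len(dets)), INFEASIBLE)
    for i, t in enumerate(tracks):
        for j, d in enumerate(dets):
            cost[i, j] = hungarian_cost(t, d, cfg.w, cfg.T,
                                        cfg.distance_scale, cfg.area_scale)
    return _solve(cost, [t.id for t in tracks])


# ---------------------------------------------------------------------------
# Kinematic filter (constant velocity on cx, cy, aspect, height)
# ---------------------------------------------------------------------------

# Noise scales relative to box height, the standard Deep SORT parameterization.
_STD_POS = 1.0 / 20.0
_STD_VEL = 1.0 / 160.0


@dataclass
class KinematicState:
    """Gaussian state of a constant-velocity filter.

    ``mean`` is either the 4-vector (cx, cy, aspect, height) or the
    8-vector with velocities appended; ``covariance`` matches. The
    measurement-space projection adds observation noise only when the state
    carries velocities (i.e. comes from the filter).
    """

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        n = self.mean.shape[0]
        if self.covariance.shape != (n, n):
            raise ValueError("covariance shape does not match mean")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")

    def projected(self) -> tuple[np.ndarray, np.ndarray]:
        """Measurement-space mean and covariance (cx, cy, aspect, height)."""
        if self.mean.shape[0] == 4:
            return self.mean, self.covariance
        h = max(self.mean[3], 1.0)
        r = np.diag(np.square([_STD_POS * h, _STD_POS * h, 1e-1, _STD_POS * h]))
        return self.mean[:4], self.covariance[:4, :4] + r


def measurement(box: BoundingBox) -> np.ndarray:
    """(cx, cy, aspect = w/h, height) observation vector of a box."""
    cx, cy = box.centroid
    return np.array([cx, cy, box.w / box.h, box.h])


def initiate_state(box: BoundingBox) -> KinematicState:
    z = measurement(box)
    h = max(box.h, 1.0)
    mean = np.concatenate([z, np.zeros(4)])
    std = [2 * _STD_POS * h, 2 * _STD_POS * h, 1e-2, 2 * _STD_POS * h,
           10 * _STD_VEL * h, 10 * _STD_VEL * h, 1e-5, 10 * _STD_VEL * h]
    return KinematicState(mean, np.diag(np.square(std)))


def predict_state(state: KinematicState) -> KinematicState:
    F = np.eye(8)
    F[:4, 4:] = np.eye(4)
    h = max(state.mean[3], 1.0)
    q = [_STD_POS * h, _STD_POS * h, 1e-2, _STD_POS * h,
         _STD_VEL * h, _STD_VEL * h, 1e-5, _STD_VEL * h]
    mean = F @ state.mean
    cov = F @ state.covariance @ F.T + np.diag(np.square(q))
    return KinematicState(mean, cov)


def update_state(state: KinematicState, box: BoundingBox) -> KinematicState:
    z = measurement(box)
    y, S = state.projected()
    H = np.zeros((4, 8))
    H[:, :4] = np.eye(4)
    K = state.covariance @ H.T @ np.linalg.inv(S)
    mean = state.mean + K @ (z - y)
    cov = (np.eye(8) - K @ H) @ state.covariance
    cov = (cov + cov.T) / 2.0
    return KinematicState(mean, cov)


def mahalanobis_distance(state: KinematicState, det: Detection) -> float:
    """Squared Mahalanobis distance of a detection from a predicted state.

    Zero iff the detection's (cx, cy, aspect, height) vector equals the
    state's projected mean; a singular covariance is an error.
    """
    y, S = state.projected()
    diff = measurement(det.box) - y
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular state covariance") from exc
    return float(diff @ sol)


# ---------------------------------------------------------------------------
# Appearance
# ---------------------------------------------------------------------------

def appearance_distance(gallery, descriptor: np.ndarray) -> float:
    """Smallest cosine distance between a descriptor and a track's gallery.

    All descriptors live on the unit hypersphere, so 1 - r.r_k is in [0, 2];
    with the non-negative histogram embedder it stays in [0, 1].
    """
    if len(gallery) == 0:
        raise ValueError("appearance distance over an empty gallery")
    r = np.asarray(descriptor, dtype=float)
    return float(min(1.0 - float(np.dot(r, np.asarray(g, dtype=float)))
                     for g in gallery))


def default_embedder(frame: np.ndarray, box: BoundingBox,
                     dim: int = 128) -> np.ndarray:
    """Unit-norm histogram descriptor of the crop under a box.

    Grayscale frames yield a ``dim``-bin intensity histogram; RGB frames an
    8 x 4 x 4 joint colour histogram (128 bins). Deterministic, and crops of
    disjoint intensity ranges give near-orthogonal descriptors.
    """
    arr = np.asarray(frame, dtype=float)
    h, w = arr.shape[:2]
    x0 = int(np.clip(np.floor(box.x), 0, w))
    x1 = int(np.clip(np.ceil(box.x + box.w), 0, w))
    y0 = int(np.clip(np.floor(box.y), 0, h))
    y1 = int(np.clip(np.ceil(box.y + box.h), 0, h))
    if x1 <= x0 or y1 <= y0:
        raise ValueError("box does not overlap the frame")
    crop = arr[y0:y1, x0:x1]
    if crop.ndim == 3:
        if dim != 128:
            raise ValueError("colour embedding is fixed at 128 bins")
        hist, _ = np.histogramdd(crop[..., :3].reshape(-1, 3),
                                 bins=(8, 4, 4),
                                 range=((0, 1), (0, 1), (0, 1)))
        hist = hist.ravel().astype(float)
    else:
        hist, _ = np.histogram(crop, bins=dim, range=(0.0, 1.0))
        # small crops fill few of the bins; smoothing along the intensity
        # axis keeps the descriptor stable under pixel noise and quantisation
        from scipy.ndimage import gaussian_filter1d
        hist = gaussian_filter1d(hist.astype(float), sigma=2.0)
    norm = np.linalg.norm(hist)
    if norm == 0:
        raise ValueError("empty crop histogram")
    return hist / norm


def deepsort_cost(track: Track, det: Detection, descriptor: np.ndarray,
                  lam: float = 0.5, mahalanobis_gate: float = 23.5127,
                  appearance_gate: float = 0.2) -> float:
    """Blended Mahalanobis / appearance cost; infeasible beyond either gate."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0,1], got {lam}")
    d1 = mahalanobis_distance(track.state, det)
    d2 = appearance_distance(track.gallery, descriptor)
    if d1 > mahalanobis_gate or d2 > appearance_gate:
        return INFEASIBLE
    return lam * d1 + (1.0 - lam) * d2


# ---------------------------------------------------------------------------
# Online trackers
# ---------------------------------------------------------------------------

class _OnlineTracker:
    """Shared bookkeeping: id allocation, miss counting, track termination."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.active: list[Track] = []
        self.finished: list[Track] = []
        self._next_id = 1
        self._last_frame: int | None = None

    def _check_frame(self, frame: int) -> None:
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(
                f"frame {frame} is not after last processed frame "
                f"{self._last_frame}")
        self._last_frame = frame

    def _new_track(self, det: Detection, **extra) -> Track:
        t = Track(id=self._next_id, assignments=[(det.frame, det.box)], **extra)
        self._next_id += 1
        self.active.append(t)
        return t

    def _age_unmatched(self, unmatched_ids: list[int]) -> None:
        still = []
        for t in self.active:
            if t.id in unmatched_ids:
                t.misses += 1
                if t.misses > self.cfg.M:
                    self.finished.append(t)
                    continue
            still.append(t)
        self.active = still

    @property
    def tracks(self) -> list[Track]:
        """All tracks created so far, finished and open, ordered by id."""
        return sorted(self.finished + self.active, key=lambda t: t.id)


class HungarianTracker(_OnlineTracker):
    """Baseline tracker: blended centroid/area cost, gate T, patience M."""

    def step(self, dets: FrameDetections, frame=None) -> AssignmentResult:
        self._check_frame(dets.frame)
        result = assign_hungarian(self.active, dets, self.cfg)
        by_id = {t.id: t for t in self.active}
        for tid, j in result.matches:
            t = by_id[tid]
            t.assignments.append((dets.frame, dets.detections[j].box))
            t.misses = 0
        self._age_unmatched(result.unmatched_tracks)
        for j in result.unmatched_detections:
            self._new_track(dets.detections[j])
        return result


class DeepSortTracker(_OnlineTracker):
    """Appearance-aware tracker: Kalman prediction + descriptor gallery.

    ``embedder(frame, box) -> descriptor`` is pluggable; the default is the
    unit-norm histogram embedder. The frame image must accompany each step.
    """

    def __init__(self, cfg: PipelineConfig, embedder=None):
        super().__init__(cfg)
        self.embedder = embedder or (
            lambda frame, box: default_embedder(frame, box, cfg.descriptor_dim))

    def step(self, dets: FrameDetections, frame=None) -> AssignmentResult:
        if frame is None and len(dets) > 0:
            raise ValueError("appearance tracker needs the frame image")
        self._check_frame(dets.frame)
        for t in self.active:
            t.state = predict_state(t.state)
        descriptors = [self.embedder(frame, d.box) for d in dets]
        cost = np.full((len(self.active), len(dets)), INFEASIBLE)
        for i, t in enumerate(self.active):
            for j, d in enumerate(dets):
                cost[i, j] = deepsort_cost(
                    t, d, descriptors[j], self.cfg.lam,
                    self.cfg.mahalanobis_gate, self.cfg.appearance_gate)
        result = _solve(cost, [t.id for t in self.active])
        by_id = {t.id: t for t in self.active}
        for tid, j in result.matches:
            t = by_id[tid]
            det = dets.detections[j]
            t.assignments.append((dets.frame, det.box))
            t.state = update_state(t.state, det.box)
            t.gallery.append(descriptors[j])
            if len(t.gallery) > self.cfg.gallery_size:
                del t.gallery[: len(t.gallery) - self.cfg.gallery_size]
            t.misses = 0
        self._age_unmatched(result.unmatched_tracks)
        for j in result.unmatched_detections:
            self._new_track(dets.detections[j],
                            state=initiate_state(dets.detections[j].box),
                            gallery=[descriptors[j]])
        return result


def make_tracker(cfg: PipelineConfig, embedder=None) -> _OnlineTracker:
    if cfg.tracker == "deepsort":
        return DeepSortTracker(cfg, embedder)
    return HungarianTracker(cfg)


def step_tracker(tracker: _OnlineTracker, dets: FrameDetections,
                 frame=None) -> list[Track]:
    """Advance a tracker by one frame and return all tracks so far."""
    tracker.step(dets, frame)
    return tracker.tracks


def track_sequence(detections: list[FrameDetections], cfg: PipelineConfig,
                   frames=None, embedder=None) -> list[Track]:
    """Run a tracker over a whole detection stream.

    Frame indices absent from ``detections`` are stepped with an empty
    detection set so that miss counters advance per frame, not per record.
    ``frames`` (indexable by frame number) is required for the appearance
    tracker.
    """
    tracker = make_tracker(cfg, embedder)
    if not detections:
        return []
    by_frame = {fd.frame: fd for fd in detections}
    first, last = min(by_frame), max(by_frame)
    for f in range(first, last + 1):
        fd = by_frame.get(f, FrameDetections(f))
        img = frames[f] if frames is not None else None
        tracker.step(fd, img)
    n_tracks = len(tracker.tracks)
    logger.info("tracked %d frames -> %d tracks (%s backend)",
                last - first + 1, n_tracks, cfg.tracker)
    return tracker.tracks
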
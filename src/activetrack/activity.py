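"""Per-frame activity measures for tracked boxes.

Three interchangeable measures score how much is happening inside a box:

* optical flow (``of``) — a block-wise Lucas-Kanade estimate of the motion
  field between consecutive frames; the activity value of a box is the
  maximum flow magnitude over its pixels. The maximum (rather than a mean)
  keeps values comparable across box sizes without area normalisation.
* interest-point density (``stip``) — spatiotemporal corners detected as
  local maxima of the Harris3D corner function H = det(mu) - k * trace(mu)^3
  over the video volume; the activity value is the count of points inside
  the box divided by the box area.
* classifier confidence (``classifier``) — a pluggable per-box scorer
  returning the active-class confidence in [0, 1].

Activity values are non-negative; larger means more active. They are only
compared within a frame (by rank), never across frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BoundingBox, Track
from .io import PipelineConfig, logger

MEASURES = ("of", "stip", "classifier")


@dataclass(frozen=True)
class ActivityRecord:
    """Activity value of one tracked box in one frame."""

    frame: int
    track_id: int
    measure: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"activity value must be >= 0, got {self.value}")
        if self.measure == "classifier" and not (0.0 <= self.value <= 1.0):
            raise ValueError(
                f"classifier confidence must lie in [0,1], got {self.value}")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")


# ---------------------------------------------------------------------------
# Optical flow (block-wise Lucas-Kanade)
# ---------------------------------------------------------------------------

def lucas_kanade_flow(frame_t: np.ndarray, frame_t1: np.ndarray,
                      block: int = 8, window: int = 16,
                      smooth_sigma: float = 1.0,
                      iterations: int = 5) -> np.ndarray:
    """Block-wise Lucas-Kanade flow from ``frame_t`` to ``frame_t1``.

    The frame is divided into ``block`` x ``block`` sections sharing one
    velocity vector each, estimated by least squares over a ``window`` x
    ``window`` support centred on the block and refined by a few
    warp-and-update iterations (which extends the usable displacement range
    beyond the ~1 px validity of a single linearisation). Rank-deficient
    blocks (no texture) get a zero vector; their count is logged.

    Returns an (H, W, 2) array of per-pixel (vx, vy) in pixels/frame, the
    block estimate replicated over its pixels.
    """
    f0 = np.asarray(frame_t, dtype=float)
    f1 = np.asarray(frame_t1, dtype=float)
    if f0.shape != f1.shape or f0.ndim != 2:
        raise ValueError("flow needs two equal-size 2-D frames")
    if smooth_sigma > 0:
        f0 = ndimage.gaussian_filter(f0, smooth_sigma)
        f1 = ndimage.gaussian_filter(f1, smooth_sigma)
    gy, gx = np.gradient(f0)
    H, W = f0.shape
    flow = np.zeros((H, W, 2))
    half = window / 2.0
    degenerate = 0
    for y0 in range(0, H, block):
        for x0 in range(0, W, block):
            cy = y0 + min(block, H - y0) / 2.0
            cx = x0 + min(block, W - x0) / 2.0
            ylo = int(np.clip(np.floor(cy - half), 0, H))
            yhi = int(np.clip(np.ceil(cy + half), 0, H))
            xlo = int(np.clip(np.floor(cx - half), 0, W))
            xhi = int(np.clip(np.ceil(cx + half), 0, W))
            wy, wx = np.mgrid[ylo:yhi, xlo:xhi]
            wy, wx = wy.ravel().astype(float), wx.ravel().astype(float)
            a_all = gx[ylo:yhi, xlo:xhi].ravel()
            b_all = gy[ylo:yhi, xlo:xhi].ravel()
            f0w = f0[ylo:yhi, xlo:xhi].ravel()
            v = np.zeros(2)
            ok = True
            res0 = res = None
            step = 0.0
            for _ in range(max(1, iterations)):
                ys, xs = wy + v[1], wx + v[0]
                # samples warped outside the frame carry no information; a
                # fit is only trusted while at least half the window stays
                # in frame (a shrinking support can shrink the residual for
                # free, masking divergence)
                valid = (ys >= 0) & (ys <= H - 1) & (xs >= 0) & (xs <= W - 1)
                if valid.sum() < max(9, 0.5 * wy.size):
                    ok = False
                    break
                a, b = a_all[valid], b_all[valid]
                G = np.array([[a @ a, a @ b], [a @ b, b @ b]])
                # smallest structure-tensor eigenvalue gates texture-less blocks
                tr = G[0, 0] + G[1, 1]
                det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
                lam_min = tr / 2 - np.sqrt(max(tr * tr / 4 - det, 0.0))
                if lam_min < 1e-9 * a.size:
                    ok = False
                    break
                f1w = ndimage.map_coordinates(f1, np.vstack([ys, xs])[:, valid],
                                              order=1, mode="nearest")
                it = f1w - f0w[valid]
                res = float(it @ it) / valid.sum()
                if res0 is None:
                    res0 = res
                dv = np.linalg.solve(G, -np.array([a @ it, b @ it]))
                v = v + dv
                step = float(np.linalg.norm(dv))
                if not np.all(np.isfinite(v)) or np.linalg.norm(v) > window:
                    ok = False
                    break
                if step < 1e-2:
                    break
            # two reliability checks: the fit must have shrunk the residual
            # (windows straddling content the translation model cannot
            # explain never do) and must not still be taking large steps
            # when the iteration budget runs out (divergence)
            if ok and res0 is not None and res0 > 0 and not res < 0.5 * res0:
                ok = False
            if ok and step > 0.3:
                ok = False
            if ok:
                flow[y0:y0 + block, x0:x0 + block, 0] = v[0]
                flow[y0:y0 + block, x0:x0 + block, 1] = v[1]
            else:
                degenerate += 1
    if degenerate:
        logger.debug("lucas_kanade_flow: %d degenerate blocks zeroed", degenerate)
    return flow


def flow_magnitude(flow: np.ndarray) -> np.ndarray:
    return np.hypot(flow[..., 0], flow[..., 1])


def activity_of(box: BoundingBox, flow: np.ndarray) -> float:
    """Maximum flow magnitude over the pixels inside a box."""
    H, W = flow.shape[:2]
    y0 = int(np.clip(np.floor(box.y), 0, H))
    y1 = int(np.clip(np.ceil(box.y + box.h), 0, H))
    x0 = int(np.clip(np.floor(box.x), 0, W))
    x1 = int(np.clip(np.ceil(box.x + box.w), 0, W))
    if y1 <= y0 or x1 <= x0:
        raise ValueError("box lies fully outside the frame")
    return float(flow_magnitude(flow[y0:y1, x0:x1]).max())


# ---------------------------------------------------------------------------
# Spatiotemporal interest points (Harris3D)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StipConfig:
    """Harris3D parameters: smoothing variances and the corner constant k."""

    sigma2: float = 4.0              # spatial variance of the scale-space kernel
    tau2: float = 2.0                # temporal variance
    s: float = 2.0                   # integration-scale factor
    k: float = 0.005                 # corner-function parameter
    response_threshold: float = 1e-15   # absolute numerical floor on H
    relative_threshold: float = 0.01    # fraction of the volume's peak H

    def __post_init__(self) -> None:
        for name in ("sigma2", "tau2", "s", "k", "response_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.relative_threshold < 0:
            raise ValueError("relative_threshold must be >= 0")

    def effective_threshold(self, peak: float) -> float:
        """Detection threshold for a volume whose peak response is ``peak``.

        H scales with the sixth power of intensity contrast, so a useful
        absolute threshold would have to know the volume's contrast; the
        default is therefore relative to the peak response (the common
        Harris practice), with a tiny absolute floor to reject volumes
        whose response is numerically zero everywhere.
        """
        return max(self.response_threshold, self.relative_threshold * peak)

    @classmethod
    def from_pipeline(cls, cfg: PipelineConfig) -> "StipConfig":
        return cls(cfg.stip_sigma2, cfg.stip_tau2, cfg.stip_s, cfg.stip_k,
                   cfg.stip_response_threshold, cfg.stip_relative_threshold)


@dataclass(frozen=True)
class Stip:
    """One spatiotemporal interest point (x, y in px; t in frames)."""

    x: float
    y: float
    t: float
    response: float


def harris3d_response(volume: np.ndarray, cfg: StipConfig) -> np.ndarray:
    """Dense corner function H over a (t, y, x) video volume.

    Scale-space L by separable Gaussian smoothing with variances
    (tau2, sigma2, sigma2); first derivatives by central differences
    (one-sided at the boundary frames); second-moment matrix entries
    smoothed at the integration scales (s * tau2, s * sigma2); then
    H = det(mu) - k * trace(mu)^3.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be (t, y, x)")
    if vol.shape[0] < 3:
        raise ValueError("volume must span at least 3 frames")
    sig = (np.sqrt(cfg.tau2), np.sqrt(cfg.sigma2), np.sqrt(cfg.sigma2))
    L = ndimage.gaussian_filter(vol, sig)
    Lt, Ly, Lx = np.gradient(L)
    isig = (np.sqrt(cfg.s * cfg.tau2),
            np.sqrt(cfg.s * cfg.sigma2), np.sqrt(cfg.s * cfg.sigma2))
    sm = lambda a: ndimage.gaussian_filter(a, isig)
    a, d, f = sm(Lx * Lx), sm(Ly * Ly), sm(Lt * Lt)
    b, c, e = sm(Lx * Ly), sm(Lx * Lt), sm(Ly * Lt)
    det = a * (d * f - e * e) - b * (b * f - e * c) + c * (b * e - d * c)
    trace = a + d + f
    return det - cfg.k * trace ** 3


def harris3d(volume: np.ndarray, cfg: StipConfig | None = None) -> list[Stip]:
    """Detect interest points: strict 26-neighbourhood local maxima of H
    above the response threshold. A temporally constant volume yields none
    (the temporal derivative vanishes, so det(mu) = 0 and H <= 0).
    """
    cfg = cfg or StipConfig()
    H = harris3d_response(volume, cfg)
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh = ndimage.maximum_filter(H, footprint=footprint,
                                   mode="constant", cval=-np.inf)
    mask = (H > neigh) & (H > cfg.effective_threshold(float(H.max())))
    ts, ys, xs = np.nonzero(mask)
    stips = [Stip(float(x), float(y), float(t), float(H[t, y, x]))
             for t, y, x in zip(ts, ys, xs)]
    logger.debug("harris3d: %d interest points in %s volume",
                 len(stips), volume.shape)
    return stips


def stips_by_frame(stips: list[Stip]) -> dict[int, list[Stip]]:
    """Bucket interest points by nearest-integer frame."""
    out: dict[int, list[Stip]] = {}
    for s in stips:
        out.setdefault(int(round(s.t)), []).append(s)
    return out


def activity_stip(box: BoundingBox, stips_at_frame: list[Stip]) -> float:
    """Interest-point density: count inside the box over the box area."""
    n = sum(1 for s in stips_at_frame if box.contains_point(s.x, s.y))
    return n / box.area


# ---------------------------------------------------------------------------
# Classifier confidence
# ---------------------------------------------------------------------------

def activity_classifier(box: BoundingBox, scorer, frame: int = 0) -> float:
    """Active-class confidence of a box from a pluggable scorer.

    ``scorer(frame, box)`` must return a value in [0, 1]; anything else is
    an error. An active/inactive decision, when wanted, is the comparison
    ``value >= threshold`` with the configured classifier threshold.
    """
    value = float(scorer(frame, box))
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"scorer returned {value}, outside [0,1]")
    return value


# ---------------------------------------------------------------------------
# Scoring tracked boxes
# ---------------------------------------------------------------------------

def boxes_at_frame(tracks: list[Track], frame: int) -> list[tuple[int, BoundingBox]]:
    """(track id, box) pairs of every track detected on a frame."""
    out = []
    for t in tracks:
        box = t.box_at(frame)
        if box is not None:
            out.append((t.id, box))
    return out


def score_frame(tracked_boxes: list[tuple[int, BoundingBox]], measure: str,
                frame: int, *, flow: np.ndarray | None = None,
                stips: list[Stip] | None = None,
                scorer=None) -> list[ActivityRecord]:
    """One activity record per tracked box on a frame, by the chosen measure."""
    if measure == "of":
        if flow is None:
            raise ValueError("measure 'of' needs a flow field")
        val = lambda box: activity_of(box, flow)
    elif measure == "stip":
        if stips is None:
            raise ValueError("measure 'stip' needs the frame's interest points")
        val = lambda box: activity_stip(box, stips)
    elif measure == "classifier":
        if scorer is None:
            raise ValueError("measure 'classifier' needs a scorer")
        val = lambda box: activity_classifier(box, scorer, frame)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    seen = set()
    records = []
    for tid, box in tracked_boxes:
        if tid in seen:
            raise ValueError(f"duplicate track id {tid} on frame {frame}")
        seen.add(tid)
        records.append(ActivityRecord(frame, tid, measure, val(box)))
    return records


def score_tracks(frames, tracks: list[Track], cfg: PipelineConfig,
                 scorer=None) -> list[ActivityRecord]:
    """Score every tracked box of a sequence with the configured measure.

    For the flow measure, frame t is scored against the (t, t+1) flow
    field; the final frame reuses the (t-1, t) field so every frame ranks.
    For the interest-point measure the detector runs once over the whole
    volume. ``frames`` is the full list of grayscale frames (may be None
    for the classifier measure).
    """
    frames_with_boxes = sorted({f for t in tracks for f in t.frames})
    if not frames_with_boxes:
        return []
    records: list[ActivityRecord] = []
    if cfg.measure == "stip":
        stips = harris3d(np.stack(frames), StipConfig.from_pipeline(cfg))
        buckets = stips_by_frame(stips)
        for f in frames_with_boxes:
            records.extend(score_frame(boxes_at_frame(tracks, f), "stip", f,
                                       stips=buckets.get(f, [])))
    elif cfg.measure == "of":
        n = len(frames)
        for f in frames_with_boxes:
            if f + 1 < n:
                src, dst = f, f + 1
            elif f > 0:
                src, dst = f - 1, f     # last frame: reuse the previous pair
            else:
                raise ValueError("flow measure needs at least 2 frames")
            flow = lucas_kanade_flow(frames[src], frames[dst],
                                     cfg.flow_block, cfg.flow_window,
                                     cfg.flow_smooth_sigma,
                                     cfg.flow_iterations)
            records.extend(score_frame(boxes_at_frame(tracks, f), "of", f,
                                       flow=flow))
    elif cfg.measure == "classifier":
        for f in frames_with_boxes:
            records.extend(score_frame(boxes_at_frame(tracks, f),
                                       "classifier", f, scorer=scorer))
    else:
        raise ValueError(f"unknown measure {cfg.measure!r}")
    return records
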
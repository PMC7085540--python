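"""Synthetic scenes with full ground truth for offline testing.

A scene is a static textured background with textured rectangular sprites
moving along waypoint trajectories; exactly one sprite is designated
active and moves markedly faster with frequent direction reversals (the
premise being that the subject of interest makes more sudden movements).
Sprites carry random-noise textures with short-range correlation: flat
colour would defeat gradient-based flow estimation (aperture problem),
while pure white noise would defeat its linearisation, so textures are
seeded noise smoothed over a couple of pixels.

``perturb_detections`` turns the exact ground-truth boxes into a realistic
detection stream: per-box dropout, Gaussian corner jitter, Poisson false
positives, and drawn confidences. All randomness flows through explicit
seeds; identical seeds give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BoundingBox, Detection, FrameDetections, Track
from .io import logger


@dataclass
class SpriteSpec:
    """One moving sprite: size, texture seed, waypoint trajectory, speed."""

    id: int
    size: tuple[int, int]                 # (w, h) px
    texture_seed: int
    waypoints: list[tuple[float, float]]  # top-left corner positions
    speed: float                          # px/frame along the polyline
    active: bool = False
    ping_pong: bool = True                # bounce between the waypoint ends

    def positions(self, n_frames: int) -> list[tuple[float, float]]:
        """Top-left corner per frame, walking the polyline at ``speed``."""
        if len(self.waypoints) < 2 or self.speed == 0:
            return [self.waypoints[0]] * n_frames
        pts = [np.asarray(p, dtype=float) for p in self.waypoints]
        pos = pts[0].copy()
        target = 1
        direction = 1
        out = [tuple(pos)]
        for _ in range(n_frames - 1):
            remaining = self.speed
            while remaining > 1e-12:
                to_target = pts[target] - pos
                dist = float(np.linalg.norm(to_target))
                if dist <= remaining:
                    pos = pts[target].copy()
                    remaining -= dist
                    nxt = target + direction
                    if nxt < 0 or nxt >= len(pts):
                        if self.ping_pong:
                            direction = -direction
                            nxt = target + direction
                        else:
                            remaining = 0.0
                            break
                    target = nxt
                else:
                    pos = pos + to_target / dist * remaining
                    remaining = 0.0
            out.append(tuple(pos))
        return out


@dataclass
class SceneConfig:
    frame_size: tuple[int, int]           # (width, height)
    n_frames: int
    sprites: list[SpriteSpec]
    background_texture_seed: int = 0
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a scene needs at least 2 frames")
        if sum(s.active for s in self.sprites) != 1:
            raise ValueError("exactly one sprite must be active")
        ids = [s.id for s in self.sprites]
        if len(set(ids)) != len(ids):
            raise ValueError("sprite ids must be unique")
        W, H = self.frame_size
        for s in self.sprites:
            w, h = s.size
            for f, (x, y) in enumerate(s.positions(self.n_frames)):
                if x < 0 or y < 0 or x + w > W or y + h > H:
                    raise ValueError(
                        f"sprite {s.id} leaves the frame at frame {f} "
                        f"(pos {(x, y)}, size {s.size})")


@dataclass
class SceneTruth:
    """Ground truth: per-frame box of every sprite plus the active identity."""

    frame_size: tuple[int, int]
    n_frames: int
    boxes: dict[int, dict[int, BoundingBox]]   # sprite id -> frame -> box
    active_id: int

    def gt_tracks(self) -> dict[int, Track]:
        return {sid: Track(id=sid,
                           assignments=[(f, per_frame[f])
                                        for f in sorted(per_frame)])
                for sid, per_frame in self.boxes.items()}

    def active_track(self) -> Track:
        return self.gt_tracks()[self.active_id]

    def detections(self) -> list[FrameDetections]:
        """The exact ground-truth boxes as a perfect detection stream."""
        out = []
        for f in range(self.n_frames):
            dets = [Detection(f, per_frame[f])
                    for sid, per_frame in sorted(self.boxes.items())
                    if f in per_frame]
            out.append(FrameDetections(f, dets))
        return out

    def active_flags(self) -> dict[int, BoundingBox]:
        return dict(self.boxes[self.active_id])


def _texture(shape: tuple[int, int], seed: int, lo: float, hi: float,
             corr_sigma: float = 1.5) -> np.ndarray:
    """Seeded noise texture with ~corr_sigma px correlation, scaled to [lo, hi]."""
    rng = np.random.default_rng(seed)
    t = ndimage.gaussian_filter(rng.uniform(size=shape), corr_sigma)
    t -= t.min()
    span = t.max() - t.min()
    if span > 0:
        t /= span
    return lo + (hi - lo) * t


def generate_scene(cfg: SceneConfig) -> tuple[list[np.ndarray], SceneTruth]:
    """Render the frames of a scene and emit its ground truth.

    Sprites are pasted at integer-rounded positions (the emitted boxes use
    the same rounded coordinates, so ground truth is pixel-aligned);
    Gaussian pixel noise of sd ``noise_sd`` is added per frame.
    Deterministic for a given config.
    """
    W, H = cfg.frame_size
    background = _texture((H, W), cfg.background_texture_seed, 0.35, 0.55)
    textures = {s.id: _texture((s.size[1], s.size[0]), s.texture_seed,
                               0.05, 0.95)
                for s in cfg.sprites}
    positions = {s.id: s.positions(cfg.n_frames) for s in cfg.sprites}
    noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    frames = []
    boxes: dict[int, dict[int, BoundingBox]] = {s.id: {} for s in cfg.sprites}
    active_id = next(s.id for s in cfg.sprites if s.active)
    for f in range(cfg.n_frames):
        frame = background.copy()
        for s in cfg.sprites:
            x, y = positions[s.id][f]
            xi, yi = int(round(x)), int(round(y))
            w, h = s.size
            frame[yi:yi + h, xi:xi + w] = textures[s.id]
            boxes[s.id][f] = BoundingBox(float(xi), float(yi),
                                         float(w), float(h))
        if cfg.noise_sd > 0:
            frame = frame + noise_rng.normal(0.0, cfg.noise_sd, frame.shape)
        frames.append(np.clip(frame, 0.0, 1.0))
    logger.info("generated scene: %d frames %dx%d, %d sprites, active id %d",
                cfg.n_frames, W, H, len(cfg.sprites), active_id)
    return frames, SceneTruth((W, H), cfg.n_frames, boxes, active_id)


def default_scene_config(seed: int = 0, n_sprites: int = 5,
                         n_frames: int = 60,
                         frame_size: tuple[int, int] = (160, 120),
                         active_speed: float = 3.0,
                         base_speed: float = 1.0,
                         noise_sd: float = 0.01) -> SceneConfig:
    """The standard study scene: well-separated sprites, one at 3x speed.

    Sprites are confined to disjoint cells of a grid so identities are
    unambiguous; the active sprite oscillates between two waypoints at
    ``active_speed`` (frequent direction reversals), the rest drift at
    ``base_speed``.
    """
    if n_sprites > 6:
        raise ValueError("the default grid holds at most 6 sprites")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    W, H = frame_size
    cell_w, cell_h = W // 3, H // 2
    cells = [(cx * cell_w, cy * cell_h) for cy in range(2) for cx in range(3)]
    rng.shuffle(cells)
    active_index = int(rng.integers(n_sprites))
    sprites = []
    for i in range(n_sprites):
        cx0, cy0 = cells[i]
        w = int(rng.integers(12, 17))
        h = int(rng.integers(16, 21))
        margin = 3
        x_lo, x_hi = cx0 + margin, cx0 + cell_w - margin - w
        y_lo, y_hi = cy0 + margin, cy0 + cell_h - margin - h
        start = (float(rng.uniform(x_lo, x_lo + 4)),
                 float(rng.uniform(y_lo, y_lo + 4)))
        active = i == active_index
        if active:
            # short-period oscillation: direction reversal every few frames
            end = (start[0] + min(12.0, x_hi - start[0]),
                   start[1] + min(8.0, y_hi - start[1]))
        else:
            end = (float(rng.uniform(x_hi - 4, x_hi)),
                   float(rng.uniform(y_hi - 4, y_hi)))
        sprites.append(SpriteSpec(
            id=i + 1, size=(w, h), texture_seed=int(seed * 101 + i),
            waypoints=[start, end],
            speed=active_speed if active else base_speed,
            active=active))
    return SceneConfig(frame_size=frame_size, n_frames=n_frames,
                       sprites=sprites, background_texture_seed=seed * 17 + 5,
                       noise_sd=noise_sd, seed=seed)


def _default_conf_model(rng: np.random.Generator) -> float:
    return float(np.clip(rng.normal(0.85, 0.07), 0.0, 1.0))


def perturb_detections(truth: SceneTruth, jitter_sd: float = 1.0,
                       dropout_p: float = 0.05, fp_rate: float = 0.2,
                       conf_model=None, seed: int = 0) -> list[FrameDetections]:
    """Degrade ground-truth boxes into a realistic detection stream.

    Each box is independently dropped with probability ``dropout_p``; the
    surviving boxes get Gaussian jitter of sd ``jitter_sd`` on each corner
    coordinate; Poisson(``fp_rate``) false boxes per frame are added at
    random positions; confidences come from ``conf_model(rng)``.
    """
    if not (0.0 <= dropout_p <= 1.0):
        raise ValueError("dropout_p must lie in [0,1]")
    conf_model = conf_model or _default_conf_model
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    W, H = truth.frame_size
    out = []
    for f in range(truth.n_frames):
        dets = []
        for sid in sorted(truth.boxes):
            box = truth.boxes[sid].get(f)
            if box is None:
                continue
            if dropout_p > 0 and rng.uniform() < dropout_p:
                continue
            x0, y0 = box.x, box.y
            x1, y1 = box.x + box.w, box.y + box.h
            if jitter_sd > 0:
                x0, y0, x1, y1 = (v + rng.normal(0.0, jitter_sd)
                                  for v in (x0, y0, x1, y1))
            w = max(x1 - x0, 1.0)
            h = max(y1 - y0, 1.0)
            dets.append(Detection(f, BoundingBox(x0, y0, w, h),
                                  conf_model(rng)))
        for _ in range(rng.poisson(fp_rate)):
            w = float(rng.uniform(8, 30))
            h = float(rng.uniform(8, 30))
            x = float(rng.uniform(0, max(W - w, 1)))
            y = float(rng.uniform(0, max(H - h, 1)))
            dets.append(Detection(f, BoundingBox(x, y, w, h),
                                  conf_model(rng)))
        out.append(FrameDetections(f, dets))
    return out


def oracle_scorer(truth: SceneTruth):
    """Perfect active-class scorer: confidence = IoU with the active box.

    A test double for the classifier measure — returns, for a query box on
    a frame, its IoU with the ground-truth active box of that frame (0 when
    the active subject is absent).
    """
    from .core import iou

    active = truth.boxes[truth.active_id]

    def scorer(frame: int, box: BoundingBox) -> float:
        gt = active.get(frame)
        return iou(box, gt) if gt is not None else 0.0

    return scorer
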
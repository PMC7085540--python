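"""On-disk artifacts: detection/track/ground-truth CSV, frames, config, logging.

File dialect
------------
Detections, tracks and ground truth all share one MOT-style CSV dialect::

    frame,id,x,y,w,h,conf,label[,active]

``frame`` is 1-based in files (the MOT convention) and converted to 0-based
at this boundary; ``id`` is -1 for raw, untracked detections; the optional
trailing ``active`` column (0/1) marks the ground-truth active subject.
A header row is written on output and skipped on input when present.

Activity tables use ``frame,track_id,measure,value,rank,is_active``.

Frames are loaded from a directory of images (lexicographic order) or a
video container, as grayscale float arrays in [0, 1]; RGB input is reduced
to luma with the Rec. 601 weights (0.299, 0.587, 0.114).
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import BoundingBox, Detection, FrameDetections, Track

logger = logging.getLogger("activetrack")

_HEADER = ["frame", "id", "x", "y", "w", "h", "conf", "label", "active"]

#: Rec. 601 luma weights applied to RGB input.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    root = logging.getLogger("activetrack")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)
    root.setLevel(level)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable parameter of the pipeline, with its default.

    Defaults follow the method's published operating point where one is
    stated (confidence threshold 0.55; assignment gate T = 100 px;
    termination patience M = 20 frames; appearance gallery of 100
    descriptors of length 128; corner parameter k = 0.005; activity-match
    minimum IoU 10%; track-level thresholds alpha = theta = 50%), and are
    documented package choices otherwise.
    """

    # detection ingestion
    detection_conf_threshold: float = 0.55
    detection_label: str = "person"

    # tracking
    tracker: str = "hungarian"          # {"hungarian", "deepsort"}
    w: float = 0.5                       # distance-vs-area weight, Hungarian cost
    T: float = 100.0                     # centroid-distance gate, px
    M: int = 20                          # termination patience, frames
    distance_scale: float = 1.0          # optional scale on the centroid term
    area_scale: float = 1.0              # optional scale on the area term
    lam: float = 0.5                     # Mahalanobis-vs-appearance weight
    # chi-square 0.9999 quantile, 4 dof: loose enough that the sudden
    # direction changes of an active subject (which a constant-velocity
    # model underpredicts) do not fragment its own track
    mahalanobis_gate: float = 23.5127
    appearance_gate: float = 0.2
    gallery_size: int = 100
    descriptor_dim: int = 128

    # activity
    measure: str = "of"                  # {"of", "stip", "classifier"}
    flow_block: int = 8                  # px, one flow vector per block
    flow_window: int = 16                # px, least-squares support
    flow_smooth_sigma: float = 1.0       # presmoothing before gradients, px
    flow_iterations: int = 5             # warp-and-refine steps
    stip_sigma2: float = 4.0             # spatial variance
    stip_tau2: float = 2.0               # temporal variance
    stip_s: float = 2.0                  # integration-scale factor
    stip_k: float = 0.005                # corner-function parameter
    stip_response_threshold: float = 1e-15   # absolute floor on H
    stip_relative_threshold: float = 0.01    # fraction of peak H
    classifier_threshold: float = 0.5

    # evaluation
    alpha: float = 0.5                   # per-frame IoU threshold, track level
    theta: float = 0.5                   # fraction of frames, track level
    min_activity_iou: float = 0.1
    detection_iou: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_conf_threshold", "w", "lam", "alpha", "theta",
                     "min_activity_iou", "detection_iou"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for name in ("T", "M", "gallery_size", "descriptor_dim",
                     "stip_sigma2", "stip_tau2", "stip_s", "stip_k",
                     "stip_response_threshold", "flow_block", "flow_window"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.tracker not in ("hungarian", "deepsort"):
            raise ValueError(f"unknown tracker {self.tracker!r}")
        if self.measure not in ("of", "stip", "classifier"):
            raise ValueError(f"unknown measure {self.measure!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Detection / track / ground-truth CSV
# ---------------------------------------------------------------------------

def _parse_row(row: list[str], lineno: int):
    """Parse one CSV row; returns (frame0, id, Detection-fields, active) or None."""
    if len(row) < 7:
        logger.warning("line %d: expected >= 7 columns, got %d; row skipped",
                       lineno, len(row))
        return None
    try:
        frame = int(float(row[0]))
        ident = int(float(row[1]))
        x, y, w, h = (float(v) for v in row[2:6])
        conf = float(row[6])
    except ValueError:
        logger.warning("line %d: non-numeric field; row skipped", lineno)
        return None
    if w <= 0 or h <= 0:
        logger.warning("line %d: non-positive box size (w=%g, h=%g); row skipped",
                       lineno, w, h)
        return None
    if frame < 1:
        logger.warning("line %d: frame index %d < 1; row skipped", lineno, frame)
        return None
    label = row[7].strip() if len(row) > 7 and row[7].strip() else "person"
    active = False
    if len(row) > 8 and row[8].strip():
        active = bool(int(float(row[8])))
    conf = min(max(conf, 0.0), 1.0)
    return frame - 1, ident, BoundingBox(x, y, w, h), conf, label, active


def _is_header(row: list[str]) -> bool:
    try:
        float(row[0])
        return False
    except (ValueError, IndexError):
        return True


def read_detections(path: str | Path) -> list[FrameDetections]:
    """Read a detections CSV, grouping rows by frame (frames sorted ascending).

    Malformed rows are rejected with a logged warning carrying the line
    number; the track-id and active columns are ignored here.
    """
    groups = _read_rows(path)
    out = []
    for frame in sorted(groups):
        dets = [Detection(frame, box, conf, label)
                for _, box, conf, label, _ in groups[frame]]
        out.append(FrameDetections(frame, dets))
    return out


def read_ground_truth(path: str | Path):
    """Read a ground-truth CSV: per-id tracks plus the active id (or None).

    Returns ``(tracks, active_id)`` where ``tracks`` maps id -> Track built
    from the rows carrying that id, and ``active_id`` is the id whose rows
    are flagged active.
    """
    groups = _read_rows(path)
    by_id: dict[int, list[tuple[int, BoundingBox]]] = {}
    active_ids = set()
    for frame in sorted(groups):
        for ident, box, _conf, _label, active in groups[frame]:
            by_id.setdefault(ident, []).append((frame, box))
            if active:
                active_ids.add(ident)
    if len(active_ids) > 1:
        raise ValueError(f"multiple ids flagged active: {sorted(active_ids)}")
    tracks = {}
    for i, a in by_id.items():
        if i <= 0:
            raise ValueError(f"ground-truth rows must carry positive ids, got {i}")
        tracks[i] = Track(id=i, assignments=a)
    return tracks, (active_ids.pop() if active_ids else None)


def _read_rows(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    groups: dict[int, list] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and _is_header(row)):
                continue
            parsed = _parse_row(row, lineno)
            if parsed is None:
                continue
            frame, ident, box, conf, label, active = parsed
            groups.setdefault(frame, []).append((ident, box, conf, label, active))
    return groups


def write_detections(frames: list[FrameDetections], path: str | Path,
                     track_id: int = -1) -> None:
    """Write detections in the shared CSV dialect (id column = -1)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER[:8])
        for fd in frames:
            for d in fd:
                writer.writerow([fd.frame + 1, track_id,
                                 _fmt(d.box.x), _fmt(d.box.y),
                                 _fmt(d.box.w), _fmt(d.box.h),
                                 _fmt(d.confidence), d.label])


def write_tracks(tracks: list[Track], path: str | Path,
                 active_id: int | None = None) -> None:
    """Write tracks as one row per (frame, box) assignment, id column filled.

    When ``active_id`` is given the trailing active column flags its rows.
    """
    rows = []
    for t in tracks:
        for frame, box in t.assignments:
            rows.append((frame, t.id, box))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for frame, ident, box in rows:
            writer.writerow([frame + 1, ident,
                             _fmt(box.x), _fmt(box.y), _fmt(box.w), _fmt(box.h),
                             1, "person",
                             int(active_id is not None and ident == active_id)])


def read_tracks(path: str | Path) -> list[Track]:
    """Read a tracks CSV back into Track objects (sorted by id)."""
    tracks, _ = read_ground_truth(path)
    return [tracks[i] for i in sorted(tracks)]


def _fmt(v: float) -> str:
    return format(v, ".10g")


# ---------------------------------------------------------------------------
# Activity tables
# ---------------------------------------------------------------------------

def write_activity(records, rankings, path: str | Path) -> None:
    """Write per-frame activity records with their ranks to CSV.

    ``records`` is a list of ActivityRecord; ``rankings`` maps frame -> FrameRanking
    (may be empty, in which case rank/is_active are blank).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "track_id", "measure", "value", "rank", "is_active"])
        for r in sorted(records, key=lambda r: (r.frame, r.track_id)):
            rank = ""
            active = ""
            fr = rankings.get(r.frame) if rankings else None
            if fr is not None:
                rank = fr.ranks.get(r.track_id, "")
                active = int(fr.active_id == r.track_id)
            writer.writerow([r.frame + 1, r.track_id, r.measure,
                             _fmt(r.value), rank, active])


def read_activity(path: str | Path):
    """Read an activity CSV into (records, ranks) lists of plain tuples."""
    from .activity import ActivityRecord

    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and _is_header(row)):
                continue
            records.append(ActivityRecord(frame=int(row[0]) - 1,
                                          track_id=int(row[1]),
                                          measure=row[2],
                                          value=float(row[3])))
    return records


# ---------------------------------------------------------------------------
# Frame sources
# ---------------------------------------------------------------------------

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class SequenceSource:
    """A directory of image frames or a video file, with basic metadata."""

    path: Path
    frame_count: int
    size: tuple[int, int]       # (width, height)
    grayscale: bool

    @classmethod
    def open(cls, path: str | Path) -> "SequenceSource":
        path = Path(path)
        if path.is_dir():
            files = _frame_files(path)
            if not files:
                raise FileNotFoundError(f"no image frames under {path}")
            import imageio.v3 as iio
            first = iio.imread(files[0])
            h, w = first.shape[:2]
            return cls(path, len(files), (w, h), first.ndim == 2)
        import imageio.v3 as iio
        frames = list(iio.imiter(path))
        h, w = frames[0].shape[:2]
        return cls(path, len(frames), (w, h), frames[0].ndim == 2)


def _frame_files(directory: Path) -> list[Path]:
    return sorted(p for p in directory.iterdir()
                  if p.suffix.lower() in _IMAGE_EXTS)


def to_intensity(frame: np.ndarray) -> np.ndarray:
    """Convert one frame array to float grayscale in [0, 1]."""
    arr = np.asarray(frame)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.asarray(LUMA_WEIGHTS)
    return arr


def load_frames(src: SequenceSource | str | Path):
    """Iterate grayscale float frames in [0, 1] from a source.

    All frames must share the source's dimensions; a mismatch is a hard
    error (evidence of a corrupt or mixed sequence).
    """
    if not isinstance(src, SequenceSource):
        src = SequenceSource.open(src)
    import imageio.v3 as iio

    if src.path.is_dir():
        raw_iter = (iio.imread(p) for p in _frame_files(src.path))
    else:
        raw_iter = iio.imiter(src.path)
    w, h = src.size
    for i, raw in enumerate(raw_iter):
        if raw.shape[:2] != (h, w):
            raise ValueError(
                f"frame {i} has size {raw.shape[1::-1]}, expected {(w, h)}")
        yield to_intensity(raw)


def save_frames(frames, directory: str | Path) -> list[Path]:
    """Write float frames in [0,1] as 8-bit PNGs frame_0001.png, ..."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        arr = np.clip(np.asarray(frame), 0.0, 1.0)
        out = directory / f"frame_{i + 1:05d}.png"
        iio.imwrite(out, (arr * 255).round().astype(np.uint8))
        paths.append(out)
    return paths
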
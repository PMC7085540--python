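"""End-to-end orchestration: filter -> track -> score -> rank -> select.

``run_pipeline`` chains the stages over in-memory inputs and returns the
tracks, the selection outcome (with the active track's centroid trajectory
and a thumbnail crop index), and a manifest capturing the exact
configuration, input fingerprints and stage statistics so a run can be
reproduced and audited. Every stage's output is plain data, serialisable
through the io module.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .activity import score_tracks
from .core import BoundingBox, FrameDetections, Track
from .io import PipelineConfig, logger
from .selection import SelectionResult, select_from_records
from .tracking import track_sequence


def filter_detections(dets: list[FrameDetections], threshold: float = 0.55,
                      label: str | None = "person") -> list[FrameDetections]:
    """Keep detections of the wanted class with confidence >= threshold.

    The boundary is inclusive: a confidence exactly at the threshold is
    kept. ``label=None`` disables the class filter.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0,1]")
    out = []
    for fd in dets:
        kept = [d for d in fd
                if d.confidence >= threshold
                and (label is None or d.label == label)]
        out.append(FrameDetections(fd.frame, kept))
    return out


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    input_hashes: dict[str, str]
    stages: dict[str, dict] = field(default_factory=dict)
    version: str = __version__


@dataclass
class ActiveTrackOutput:
    """The final product: the active track plus render-ready summaries."""

    track_id: int | None
    trajectory: list[tuple[int, float, float]]       # (frame, cx, cy)
    thumbnail_index: list[tuple[int, BoundingBox]]   # (frame, box)


def _hash_detections(dets: list[FrameDetections]) -> str:
    h = hashlib.sha256()
    for fd in dets:
        for d in fd:
            h.update(f"{fd.frame},{d.box.x},{d.box.y},{d.box.w},{d.box.h},"
                     f"{d.confidence},{d.label};".encode())
    return h.hexdigest()[:16]


def _hash_frames(frames) -> str:
    h = hashlib.sha256()
    for f in frames:
        h.update(np.ascontiguousarray(np.asarray(f)))
    return h.hexdigest()[:16]


def run_pipeline(frames, detections: list[FrameDetections],
                 cfg: PipelineConfig, scorer=None,
                 ) -> tuple[list[Track], SelectionResult, RunManifest]:
    """Run every stage in order on one sequence.

    ``frames`` is the list of grayscale frame arrays; ``detections`` the
    raw per-frame detection stream; ``scorer`` the per-box active-class
    scorer, required only for the classifier measure. Any stage failure is
    re-raised with the stage name attached.
    """
    manifest = RunManifest(
        config=dataclasses.asdict(cfg), seed=cfg.seed,
        input_hashes={"detections": _hash_detections(detections),
                      "frames": _hash_frames(frames) if frames is not None else ""})

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        manifest.stages[name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return result

    filtered = stage("filter", lambda: filter_detections(
        detections, cfg.detection_conf_threshold, cfg.detection_label))
    n_in = sum(len(fd) for fd in detections)
    n_kept = sum(len(fd) for fd in filtered)
    manifest.stages["filter"].update(boxes_in=n_in, boxes_kept=n_kept)
    logger.info("filter: kept %d/%d detections at conf >= %.2f",
                n_kept, n_in, cfg.detection_conf_threshold)

    tracks = stage("track", lambda: track_sequence(filtered, cfg, frames))
    manifest.stages["track"].update(n_tracks=len(tracks),
                                    backend=cfg.tracker)

    records = stage("activity", lambda: score_tracks(frames, tracks, cfg,
                                                     scorer))
    manifest.stages["activity"].update(n_records=len(records),
                                       measure=cfg.measure)

    selection = stage("select", lambda: select_from_records(records))
    manifest.stages["select"].update(active_track_id=selection.active_track_id,
                                     wins=selection.wins)
    return tracks, selection, manifest


def active_track_output(tracks: list[Track],
                        selection: SelectionResult) -> ActiveTrackOutput:
    """Centroid polyline and crop index of the selected active track."""
    if selection.active_track_id is None:
        return ActiveTrackOutput(None, [], [])
    track = next(t for t in tracks if t.id == selection.active_track_id)
    trajectory = [(f, *b.centroid) for f, b in track.assignments]
    return ActiveTrackOutput(track.id, trajectory, list(track.assignments))
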
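"""Evaluation: detection P/R/F1, frame-level activity P/R/F1, track-level TPR%.

Three levels of scrutiny:

* detection level — greedy one-to-one IoU matching between predicted and
  ground-truth boxes per frame; a match with IoU >= the detection threshold
  (default 0.5) is a true positive.
* frame level (activity) — the predicted active box of a frame is a true
  positive iff it has the largest IoU with the ground-truth active box
  among that frame's detections AND that IoU reaches the minimum overlap
  (default 10%); localisation precision matters less here than picking the
  right subject.
* track level — a predicted active track is a true positive (TP_T) iff the
  fraction of its frames whose box overlaps the ground-truth active box at
  IoU >= alpha is at least theta (both default 50%); TPR% is 100 x the
  fraction of true-positive tracks over a test set. TPR% is monotone
  non-increasing in both alpha and theta.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import BoundingBox, FrameDetections, Track, iou


@dataclass
class FrameEvalConfig:
    min_activity_iou: float = 0.10
    detection_iou: float = 0.50

    def __post_init__(self) -> None:
        for name in ("min_activity_iou", "detection_iou"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0,1], got {v}")


@dataclass
class TrackEvalConfig:
    alpha: float = 0.50
    theta: float = 0.50

    def __post_init__(self) -> None:
        for name in ("alpha", "theta"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0,1], got {v}")


@dataclass
class EvalReport:
    """Counts and derived rates; undefined rates are reported 0 and flagged."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvalReport":
        p_def, r_def = tp + fp > 0, tp + fn > 0
        p = tp / (tp + fp) if p_def else 0.0
        r = tp / (tp + fn) if r_def else 0.0
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        return cls(tp, fp, fn, p, r, f1, p_def, r_def)


def eval_detections(pred: list[FrameDetections], gt: list[FrameDetections],
                    cfg: FrameEvalConfig | None = None) -> EvalReport:
    """Detection P/R/F1 by greedy per-frame IoU matching.

    Pairs are matched in descending IoU order, one-to-one; a pair counts as
    a true positive iff its IoU reaches the detection threshold. Leftover
    predictions are false positives, leftover ground truth false negatives.
    """
    cfg = cfg or FrameEvalConfig()
    gt_by_frame = {fd.frame: [d.box for d in fd] for fd in gt}
    pred_by_frame = {fd.frame: [d.box for d in fd] for fd in pred}
    tp = fp = fn = 0
    for frame in sorted(set(gt_by_frame) | set(pred_by_frame)):
        p_boxes = pred_by_frame.get(frame, [])
        g_boxes = gt_by_frame.get(frame, [])
        pairs = sorted(((iou(p, g), i, j)
                        for i, p in enumerate(p_boxes)
                        for j, g in enumerate(g_boxes)),
                       key=lambda t: (-t[0], t[1], t[2]))
        used_p: set[int] = set()
        used_g: set[int] = set()
        matched = 0
        for val, i, j in pairs:
            if val < cfg.detection_iou:
                break
            if i in used_p or j in used_g:
                continue
            used_p.add(i)
            used_g.add(j)
            matched += 1
        tp += matched
        fp += len(p_boxes) - matched
        fn += len(g_boxes) - matched
    return EvalReport.from_counts(tp, fp, fn)


def eval_frame_activity(active_pred: dict[int, BoundingBox | None],
                        gt_active: dict[int, BoundingBox | None],
                        detections: dict[int, list[BoundingBox]],
                        cfg: FrameEvalConfig | None = None) -> EvalReport:
    """Frame-level activity P/R/F1 under the largest-IoU criterion.

    Per frame: a predicted active box is TP iff, among that frame's
    detected boxes, it has the (strictly unbeaten) largest IoU with the
    ground-truth active box and that IoU >= the minimum overlap. A wrong or
    missing prediction where ground truth exists is a FN (a wrong one also
    a FP); a prediction where no ground truth exists is a FP.
    """
    cfg = cfg or FrameEvalConfig()
    tp = fp = fn = 0
    for frame in sorted(set(active_pred) | set(gt_active)):
        pred_box = active_pred.get(frame)
        gt_box = gt_active.get(frame)
        if gt_box is None:
            if pred_box is not None:
                fp += 1
            continue
        if pred_box is None:
            fn += 1
            continue
        pred_iou = iou(pred_box, gt_box)
        best = max((iou(b, gt_box) for b in detections.get(frame, [])),
                   default=0.0)
        if pred_iou >= cfg.min_activity_iou and pred_iou >= best:
            tp += 1
        else:
            fp += 1
            fn += 1
    return EvalReport.from_counts(tp, fp, fn)


def eval_track(track: Track, gt_track: Track,
               cfg: TrackEvalConfig | None = None) -> int:
    """Track-level true-positive indicator TP_T.

    Each frame of the evaluated track scores f = 1 iff its box overlaps the
    ground-truth box of the same frame at IoU >= alpha (f = 0 where ground
    truth is absent). Returns 1 iff the mean of f over the track's frames
    is >= theta. The denominator is the evaluated track's length.
    """
    cfg = cfg or TrackEvalConfig()
    if not track.assignments:
        raise ValueError("cannot evaluate an empty track")
    hits = 0
    for frame, box in track.assignments:
        gt_box = gt_track.box_at(frame)
        if gt_box is not None and iou(box, gt_box) >= cfg.alpha:
            hits += 1
    return int(hits / len(track.assignments) >= cfg.theta)


def tpr_percent(track_results: list[int]) -> float:
    """Percentage of true-positive tracks over a test set (100 x mean)."""
    if not track_results:
        raise ValueError("tpr_percent of an empty result list")
    if any(r not in (0, 1) for r in track_results):
        raise ValueError("track results must be 0/1 indicators")
    return 100.0 * sum(track_results) / len(track_results)


def per_frame_iou_table(track: Track, gt_track: Track) -> list[tuple[int, float]]:
    """(frame, IoU) rows for auditing a track evaluation."""
    return [(frame, iou(box, gt_track.box_at(frame)) if
             gt_track.box_at(frame) is not None else 0.0)
            for frame, box in track.assignments]
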
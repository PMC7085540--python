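"""Rank aggregation: from per-frame activity values to the active track.

Within each frame the tracked boxes are ranked by activity (rank 1 =
highest, competition ranking for ties). A frame's active track is the
unique rank-1 track; when the top value is shared, no track is active in
that frame. Per-track rank sequences are the track score vectors; a "win"
is a frame where the track holds rank 1 alone, and the sequence's active
track is the one with the most wins. Because only ranks matter, the
selection is invariant under any strictly monotone transformation of the
activity values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .activity import ActivityRecord
from .io import logger


@dataclass
class FrameRanking:
    """Activity ranks of one frame; active_id is None on a tied maximum."""

    frame: int
    ranks: dict[int, int]
    active_id: int | None


@dataclass
class ScoreVector:
    """A track's per-frame ranks (frames where it was detected) and win count."""

    track_id: int
    ranks: dict[int, int] = field(default_factory=dict)
    wins: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.ranks)


@dataclass
class SelectionResult:
    """The sequence-level outcome: which track is active, and why."""

    active_track_id: int | None
    wins: dict[int, int]
    active_per_frame: dict[int, int | None]

    @property
    def no_active_track(self) -> bool:
        return self.active_track_id is None


def rank_frame(records: list[ActivityRecord]) -> FrameRanking:
    """Competition-rank one frame's records by descending activity.

    Ties share the higher rank (1, 2, 2, 4 pattern); the frame's active
    track is the rank-1 track unless the maximum is shared, in which case
    none is marked active.
    """
    if not records:
        raise ValueError("cannot rank an empty frame")
    frame = records[0].frame
    ids = [r.track_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate track ids in frame {frame} records")
    if any(r.frame != frame for r in records):
        raise ValueError("records from multiple frames passed to rank_frame")
    ordered = sorted(records, key=lambda r: -r.value)
    ranks: dict[int, int] = {}
    for pos, rec in enumerate(ordered):
        if pos > 0 and rec.value == ordered[pos - 1].value:
            ranks[rec.track_id] = ranks[ordered[pos - 1].track_id]
        else:
            ranks[rec.track_id] = pos + 1
    top_value = ordered[0].value
    tied_top = len(ordered) > 1 and ordered[1].value == top_value
    active_id = None if tied_top else ordered[0].track_id
    return FrameRanking(frame, ranks, active_id)


def accumulate(rankings: list[FrameRanking]) -> list[ScoreVector]:
    """Aggregate frame rankings into per-track score vectors with win counts.

    Frames where a track was not detected contribute no rank; a tied top
    contributes a win to nobody.
    """
    frames = [fr.frame for fr in rankings]
    if any(b >= a for a, b in zip(frames[1:], frames)):
        raise ValueError("frame rankings must be in strictly increasing order")
    vectors: dict[int, ScoreVector] = {}
    for fr in rankings:
        for tid, rank in fr.ranks.items():
            sv = vectors.setdefault(tid, ScoreVector(tid))
            sv.ranks[fr.frame] = rank
            if rank == 1 and fr.active_id == tid:
                sv.wins += 1
    return [vectors[tid] for tid in sorted(vectors)]


def select_active(score_vectors: list[ScoreVector],
                  rankings: list[FrameRanking] | None = None) -> SelectionResult:
    """Pick the track with the most wins as the sequence's active track.

    Ties are broken toward the track detected in more frames, then the
    lower id. When no track ever wins a frame, the result is flagged as
    having no active track.
    """
    if not score_vectors:
        raise ValueError("no score vectors to select from")
    wins = {sv.track_id: sv.wins for sv in score_vectors}
    best = max(score_vectors, key=lambda sv: (sv.wins, sv.n_frames, -sv.track_id))
    active = best.track_id if best.wins > 0 else None
    per_frame = {fr.frame: fr.active_id for fr in rankings} if rankings else {}
    if active is None:
        logger.info("selection: no track ever ranked first alone")
    else:
        logger.info("selection: track %d active with %d wins", active,
                    wins[active])
    return SelectionResult(active, wins, per_frame)


def select_from_records(records: list[ActivityRecord]) -> SelectionResult:
    """Convenience path: records -> frame rankings -> score vectors -> result."""
    by_frame: dict[int, list[ActivityRecord]] = {}
    for r in records:
        by_frame.setdefault(r.frame, []).append(r)
    rankings = [rank_frame(by_frame[f]) for f in sorted(by_frame)]
    if not rankings:
        raise ValueError("no activity records to select from")
    return select_active(accumulate(rankings), rankings)
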
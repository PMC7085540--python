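"""Geometry primitives and the shared data model.

Coordinate convention: raster axes — origin at the top-left corner, x
rightward, y downward, 0-based. A box occupies the half-open region
``[x, x + w) x [y, y + h)``; all geometry (centroids, areas, overlaps) is
computed on the continuous boxes, never on a pixel quantisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with positive width and height.

    The centroid ``C`` and area ``P`` are the two derived quantities the
    tracker's assignment cost is built from.
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h

    def contains_point(self, px: float, py: float) -> bool:
        """Membership in the half-open region [x, x+w) x [y, y+h)."""
        return self.x <= px < self.x + self.w and self.y <= py < self.y + self.h


@dataclass(frozen=True)
class Detection:
    """One detector output: a box on a frame with a confidence and class label."""

    frame: int
    box: BoundingBox
    confidence: float = 1.0
    label: str = "person"

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0,1], got {self.confidence}")
        if self.frame < 0:
            raise ValueError(f"frame index must be >= 0, got {self.frame}")


@dataclass
class FrameDetections:
    """All detections of one frame (the set F the assignment runs over)."""

    frame: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        for d in self.detections:
            if d.frame != self.frame:
                raise ValueError(
                    f"detection on frame {d.frame} placed in FrameDetections "
                    f"for frame {self.frame}"
                )

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)


@dataclass
class Track:
    """A persistent identity: ordered (frame, box) assignments plus tracker state.

    ``misses`` counts consecutive frames without an assignment; the tracker
    closes the track once it exceeds the termination patience M.  ``gallery``
    holds the most recent appearance descriptors (bounded; oldest evicted
    first) and is only populated by the appearance-aware tracker.  ``state``
    is the kinematic filter state, opaque to everything but the tracker.
    """

    id: int
    assignments: list[tuple[int, BoundingBox]] = field(default_factory=list)
    misses: int = 0
    gallery: list = field(default_factory=list)
    state: object | None = None

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"track id must be positive, got {self.id}")
        frames = [f for f, _ in self.assignments]
        if any(b >= a for a, b in zip(frames[1:], frames)):
            raise ValueError("assignment frame indices must be strictly increasing")

    @property
    def last_frame(self) -> int:
        if not self.assignments:
            raise ValueError("track has no assignments")
        return self.assignments[-1][0]

    @property
    def last_box(self) -> BoundingBox:
        if not self.assignments:
            raise ValueError("track has no assignments")
        return self.assignments[-1][1]

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.assignments]

    def box_at(self, frame: int) -> BoundingBox | None:
        for f, b in self.assignments:
            if f == frame:
                return b
        return None

    def __len__(self) -> int:
        return len(self.assignments)


def centroid_distance(a: BoundingBox, b: BoundingBox) -> float:
    """Euclidean distance between the centroids of two boxes, in pixels."""
    (ax, ay), (bx, by) = a.centroid, b.centroid
    return math.hypot(ax - bx, ay - by)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes on continuous geometry.

    Returns a value in [0, 1]; 0 for disjoint boxes, 1 iff identical.
    """
    if a == b:      # exact, immune to (x+w)-x rounding
        return 1.0
    ix = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
    iy = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    # rounding can push the ratio a few ulp past 1 for identical boxes
    return min(inter / union, 1.0)
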
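"""Pixel-space geometry primitives underlying all association decisions.

Coordinates follow image conventions: origin at the top-left corner,
``x`` increasing rightward, ``y`` increasing downward.  Sub-pixel real
coordinates are allowed; boxes are closed regions, so containment tests
include the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["Point", "BoundingBox", "box_overlap"]


@dataclass(frozen=True)
class Point:
    """A 2-D point in pixel coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"point coordinates must be finite, got ({self.x}, {self.y})")

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle given by its top-left and bottom-right vertices."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not all(
            math.isfinite(v) for v in (self.x_min, self.y_min, self.x_max, self.y_max)
        ):
            raise ValueError("box coordinates must be finite")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def center(self) -> Point:
        return Point((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def contains(self, p: Point) -> bool:
        """Closed-region containment: points on the boundary count as inside."""
        return self.x_min <= p.x <= self.x_max and self.y_min <= p.y <= self.y_max

    def union(self, other: "BoundingBox") -> "BoundingBox":
        return BoundingBox(
            min(self.x_min, other.x_min),
            min(self.y_min, other.y_min),
            max(self.x_max, other.x_max),
            max(self.y_max, other.y_max),
        )


def box_overlap(a: BoundingBox, b: BoundingBox) -> float:
    """Area of the axis-aligned intersection of two boxes, in pixels².

    Returns 0.0 when the boxes are disjoint (touching edges count as zero
    area).  Symmetric in its arguments.  Raw intersection area is used as
    the association score — overlaps are never normalised by box area.
    """
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0.0 or h <= 0.0:
        return 0.0
    return w * h
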
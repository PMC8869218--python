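"""Axis-aligned bounding-box annotations.

One coordinate convention holds toolkit-wide: 0-based pixel coordinates,
x rightward, y downward, boxes half-open ``[x1, x2) x [y1, y2)`` so that a
pixel ``(px, py)`` lies inside a box iff ``x1 <= px < x2 and y1 <= py < y2``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BoxAnnotation:
    """A single colony's bounding box plus class label.

    ``(x1, y1)`` is the top-left corner, ``(x2, y2)`` the bottom-right
    corner (exclusive). Coordinates are pixels in the owning image.
    """

    class_id: int
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(
                f"degenerate box: ({self.x1}, {self.y1}, {self.x2}, {self.y2})"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def contains_point(self, x: float, y: float) -> bool:
        return self.x1 <= x < self.x2 and self.y1 <= y < self.y2

    def intersection(self, other: "BoxAnnotation") -> float:
        """Overlap area with ``other`` (0 if disjoint)."""
        w = min(self.x2, other.x2) - max(self.x1, other.x1)
        h = min(self.y2, other.y2) - max(self.y1, other.y1)
        return w * h if (w > 0 and h > 0) else 0.0

    def iou(self, other: "BoxAnnotation") -> float:
        inter = self.intersection(other)
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0
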
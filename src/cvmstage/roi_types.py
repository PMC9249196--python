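"""Axis-aligned region-of-interest boxes in pixel coordinates."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class RoiBox:
    """Top-left corner (x = column, y = row), size, and detector score."""

    x: int
    y: int
    width: int
    height: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box must have positive size")
        if self.x < 0 or self.y < 0:
            raise ValueError("box origin must be nonnegative")

    @property
    def x2(self) -> int:
        return self.x + self.width

    @property
    def y2(self) -> int:
        return self.y + self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    def inside(self, shape: tuple[int, int]) -> bool:
        h, w = shape[:2]
        return self.x2 <= w and self.y2 <= h

    def iou(self, other: "RoiBox") -> float:
        ix = max(0, min(self.x2, other.x2) - max(self.x, other.x))
        iy = max(0, min(self.y2, other.y2) - max(self.y, other.y))
        inter = ix * iy
        union = self.width * self.height + other.width * other.height - inter
        return inter / union if union > 0 else 0.0
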
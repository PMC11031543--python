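"""Axis-aligned bounding boxes (half-open pixel convention)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schema import LandmarkSet

__all__ = ["BoundingBox", "iou", "ground_truth_box"]


@dataclass(frozen=True)
class BoundingBox:
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    score: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate bounding box")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def ground_truth_box(landmarks: LandmarkSet, pad: float = 0.15) -> BoundingBox:
    """Nasal-base ground-truth box: the tight box over all 18 landmarks
    (which includes pronasale and both alare, the anatomical extremes),
    expanded by ``pad`` x box size on each side and clipped to the frame.

    The expansion mirrors the practice of starting detection from a box
    slightly larger than the annotated extent.
    """
    pts = landmarks.points
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate landmark extent")
    w, h = x1 - x0, y1 - y0
    x0, x1 = x0 - pad * w, x1 + pad * w
    y0, y1 = y0 - pad * h, y1 + pad * h
    fw, fh = landmarks.frame_size
    if fw > 0 and fh > 0:
        x0, y0 = max(x0, 0.0), max(y0, 0.0)
        x1, y1 = min(x1, float(fw)), min(y1, float(fh))
    return BoundingBox(x0, y0, x1, y1)
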
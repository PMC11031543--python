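"""Landmark schema and containers for basal-view nasal-base annotations.

The nasal base (alar-columellar complex) is annotated with 18 named
landmarks: two midline points (pronasale, subnasale) that define the
columellar axis, and eight left/right pairs covering the alar lobules,
nostril openings and columella.  "Left"/"right" refer to image-space
side (lower/higher x), which is fixed throughout the package.

Coordinates are pixels, origin at the top-left corner, x rightward,
y downward, 0-based; boxes are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "LandmarkSchema",
    "LandmarkSet",
    "Axis",
    "DEFAULT_SCHEMA",
    "read_annotation",
    "write_annotation",
]


@dataclass(frozen=True)
class LandmarkSchema:
    """Identity and left/right structure of the 18-landmark set.

    ``lr_pairs`` maps every lateral landmark to its mirror partner on the
    other side (an involution); ``midline_points`` lie on the columellar
    axis and have no partner.
    """

    names: tuple[str, ...]
    lr_pairs: dict[str, str]
    midline_points: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != 18:
            raise ValueError(f"schema must define exactly 18 landmarks, got {len(self.names)}")
        if len(set(self.names)) != 18:
            raise ValueError("landmark names must be unique")
        lateral = [n for n in self.names if n not in self.midline_points]
        for name in lateral:
            if name not in self.lr_pairs:
                raise ValueError(f"non-midline landmark {name!r} has no left/right partner")
        for a, b in self.lr_pairs.items():
            if self.lr_pairs.get(b) != a or a == b:
                raise ValueError("lr_pairs must be an involution without fixed points")

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def left_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n.endswith("_l"))


def _default_schema() -> LandmarkSchema:
    paired_stems = (
        "alare",
        "subalare",
        "midalar",
        "ala_outer",
        "nostril_apex",
        "nostril_base",
        "nostril_medial",
        "columella_apex",
    )
    names = ["pronasale", "subnasale"]
    pairs: dict[str, str] = {}
    for stem in paired_stems:
        l, r = f"{stem}_l", f"{stem}_r"
        names += [l, r]
        pairs[l] = r
        pairs[r] = l
    return LandmarkSchema(tuple(names), pairs, ("pronasale", "subnasale"))


#: Canonical 18-point schema used by every stage of the framework.
DEFAULT_SCHEMA = _default_schema()


@dataclass
class LandmarkSet:
    """18 sub-pixel landmark coordinates for one image.

    ``frame`` records whether the coordinates live in the whole image or
    in a nasal-base crop; ``frame_size`` is the (width, height) of that
    frame.  Landmarks pushed outside the frame by an augmentation are
    flagged in ``out_of_frame`` rather than dropped.
    """

    image_id: str
    points: np.ndarray  # (18, 2) float64, columns (x, y)
    frame: str = "whole_image"
    frame_size: tuple[int, int] = (0, 0)
    schema: LandmarkSchema = field(default_factory=lambda: DEFAULT_SCHEMA)
    out_of_frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (18, 2):
            raise ValueError(f"expected (18, 2) points, got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.frame not in ("whole_image", "crop"):
            raise ValueError(f"unknown frame {self.frame!r}")
        if self.out_of_frame is None:
            self.out_of_frame = np.zeros(18, dtype=bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[self.schema.index(name)]

    def with_points(self, points: np.ndarray, **changes) -> "LandmarkSet":
        new = replace(self, points=np.asarray(points, dtype=float), **changes)
        return new

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {n: tuple(self.points[i]) for i, n in enumerate(self.schema.names)}


@dataclass(frozen=True)
class Axis:
    """An oriented reference line: a point on the line and a unit direction."""

    point: np.ndarray
    direction: np.ndarray
    role: str = "columellar"  # or "vrl"

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis direction must be a nonzero finite vector")
        object.__setattr__(self, "direction", d / n)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        """Perpendicular signed distance of points to the line (left of
        the direction vector is positive)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        rel = pts - self.point
        normal = np.array([-self.direction[1], self.direction[0]])
        return rel @ normal

    def distance(self, pts: np.ndarray) -> np.ndarray:
        return np.abs(self.signed_distance(pts))


# ---------------------------------------------------------------------------
# labelme-compatible annotation dialect


def write_annotation(path: str | Path, landmarks: LandmarkSet, image_path: str = "") -> None:
    """Write landmarks as a labelme-compatible JSON point annotation."""
    w, h = landmarks.frame_size
    doc = {
        "imagePath": image_path or f"{landmarks.image_id}.png",
        "imageHeight": int(h),
        "imageWidth": int(w),
        "shapes": [
            {
                "label": name,
                "points": [[float(x), float(y)]],
                "shape_type": "point",
            }
            for name, (x, y) in zip(landmarks.schema.names, landmarks.points)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotation(
    path: str | Path,
    schema: LandmarkSchema = DEFAULT_SCHEMA,
    frame: str = "whole_image",
) -> LandmarkSet:
    """Read a labelme-compatible point annotation, validating it against
    the schema (all 18 landmarks present exactly once)."""
    doc = json.loads(Path(path).read_text())
    by_label: dict[str, list[float]] = {}
    for shape in doc["shapes"]:
        if shape.get("shape_type") != "point":
            continue
        label = shape["label"]
        if label in by_label:
            raise ValueError(f"duplicate landmark {label!r} in {path}")
        by_label[label] = shape["points"][0]
    missing = set(schema.names) - set(by_label)
    if missing:
        raise ValueError(f"annotation {path} is missing landmarks: {sorted(missing)}")
    pts = np.array([by_label[n] for n in schema.names], dtype=float)
    image_id = Path(doc.get("imagePath", Path(path).stem)).stem
    return LandmarkSet(
        image_id=image_id,
        points=pts,
        frame=frame,
        frame_size=(int(doc["imageWidth"]), int(doc["imageHeight"])),
        schema=schema,
    )
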
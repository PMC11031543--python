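"""Nine left/right geometry-ratio features of the nasal base.

Each feature is a ratio of a left-side measurement to the matching
right-side measurement, so a perfectly mirror-symmetric nasal base
scores 1.0 on every feature:

* ``f1``  — ratio of the angles between each nostril's long axis and the
  columellar axis (degrees);
* ``f2..f9`` — ratios of distances: midalar width, subalare-to-midline
  (VRL) distance, alare-to-columellar-axis distance, midcolumellar apex
  width, midcolumellar base width, nostril width, nostril height, and
  ala thickness.

The columellar axis is the line through pronasale and subnasale; the
vertical reference line (VRL, the facial midline surrogate inside a
basal crop) is the line through subnasale parallel to that axis.  Every
measurement's defining points are recorded in :data:`MEASUREMENT_TABLE`
so that independent re-measurement is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import Axis, LandmarkSchema, LandmarkSet, DEFAULT_SCHEMA

__all__ = [
    "GeometryFeatures",
    "FeatureScaler",
    "MEASUREMENT_TABLE",
    "columellar_axis",
    "vertical_reference_line",
    "nostril_axis_angle",
    "compute_geometry_features",
    "fit_feature_scaler",
    "normalize_features",
    "features_to_frame",
]

#: Defining landmarks of each measurement, per side.  ``kind`` is how the
#: scalar is computed: angle between nostril long axis and the columellar
#: axis; perpendicular distance of a point to an axis; distance between
#: two points; or twice the perpendicular distance of the medial nostril
#: point to the nostril's long axis (nostril width).
MEASUREMENT_TABLE: dict[int, dict] = {
    1: {"name": "nostril_axis_angle", "kind": "angle",
        "left": ("nostril_apex_l", "nostril_base_l"),
        "right": ("nostril_apex_r", "nostril_base_r")},
    2: {"name": "midalar_width", "kind": "point_to_axis", "axis": "columellar",
        "left": ("midalar_l",), "right": ("midalar_r",)},
    3: {"name": "subalare_to_midline", "kind": "point_to_axis", "axis": "vrl",
        "left": ("subalare_l",), "right": ("subalare_r",)},
    4: {"name": "alare_to_columellar_axis", "kind": "point_to_axis", "axis": "columellar",
        "left": ("alare_l",), "right": ("alare_r",)},
    5: {"name": "midcolumellar_apex_width", "kind": "point_to_axis", "axis": "columellar",
        "left": ("columella_apex_l",), "right": ("columella_apex_r",)},
    6: {"name": "midcolumellar_base_width", "kind": "point_to_axis", "axis": "columellar",
        "left": ("nostril_medial_l",), "right": ("nostril_medial_r",)},
    7: {"name": "nostril_width", "kind": "nostril_width",
        "left": ("nostril_medial_l", "nostril_apex_l", "nostril_base_l"),
        "right": ("nostril_medial_r", "nostril_apex_r", "nostril_base_r")},
    8: {"name": "nostril_height", "kind": "point_to_point",
        "left": ("nostril_apex_l", "nostril_base_l"),
        "right": ("nostril_apex_r", "nostril_base_r")},
    9: {"name": "ala_thickness", "kind": "point_to_point",
        "left": ("midalar_l", "ala_outer_l"), "right": ("midalar_r", "ala_outer_r")},
}


@dataclass
class GeometryFeatures:
    """The nine ratio features plus the raw per-side measurements.

    ``f[0]`` is the angular ratio f1; ``f[i-1]`` is feature i.  ``left``
    and ``right`` hold the underlying measurements (degrees for index 0,
    pixels otherwise) for downstream explanation overlays.
    """

    f: np.ndarray        # (9,)
    left: np.ndarray     # (9,) a_L then d_L[2..9]
    right: np.ndarray    # (9,)

    def __post_init__(self) -> None:
        for arr in (self.f, self.left, self.right):
            if np.asarray(arr).shape != (9,):
                raise ValueError("expected 9 entries per feature vector")
        if not np.all(np.isfinite(self.f)) or np.any(self.f <= 0):
            raise ValueError("geometry features must be strictly positive and finite")


def columellar_axis(landmarks: LandmarkSet) -> Axis:
    """Axis through pronasale and subnasale, oriented subnasale -> pronasale."""
    prn = landmarks["pronasale"]
    sn = landmarks["subnasale"]
    d = prn - sn
    if np.linalg.norm(d) == 0:
        raise ValueError("invalid annotation: pronasale and subnasale coincide")
    return Axis(point=sn, direction=d, role="columellar")


def vertical_reference_line(landmarks: LandmarkSet) -> Axis:
    """Facial-midline surrogate: line through subnasale parallel to the
    columellar axis (nasion/gnathion are outside a basal crop)."""
    ax = columellar_axis(landmarks)
    return Axis(point=landmarks["subnasale"], direction=ax.direction, role="vrl")


def nostril_axis_angle(apex: np.ndarray, base: np.ndarray, axis: Axis) -> float:
    """Unsigned angle (degrees, in [0, 180]) between the base->apex nostril
    long axis and the columellar axis direction."""
    v = np.asarray(apex, float) - np.asarray(base, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate anatomy: nostril apex and base coincide")
    u = axis.direction
    cross = v[0] * u[1] - v[1] * u[0]
    dot = float(v @ u)
    return float(np.degrees(np.arctan2(abs(cross), dot)))


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ax = Axis(point=a, direction=np.asarray(b, float) - np.asarray(a, float))
    return float(ax.distance(p)[0])


def _measure_side(landmarks: LandmarkSet, spec: dict, side: str,
                  col_axis: Axis, vrl: Axis) -> float:
    pts = [landmarks[name] for name in spec[side]]
    kind = spec["kind"]
    if kind == "angle":
        return nostril_axis_angle(pts[0], pts[1], col_axis)
    if kind == "point_to_axis":
        axis = col_axis if spec["axis"] == "columellar" else vrl
        return float(axis.distance(pts[0])[0])
    if kind == "point_to_point":
        return float(np.linalg.norm(pts[0] - pts[1]))
    if kind == "nostril_width":
        medial, apex, base = pts
        return 2.0 * _point_line_distance(medial, apex, base)
    raise ValueError(f"unknown measurement kind {kind!r}")


def compute_geometry_features(
    landmarks: LandmarkSet, schema: LandmarkSchema = DEFAULT_SCHEMA
) -> GeometryFeatures:
    """Compute f1..f9 (left/right measurement ratios) from an 18-point set.

    Raises if any right-side measurement is zero (degenerate anatomy) or
    the columellar axis is undefined.
    """
    if landmarks.schema.names != schema.names:
        raise ValueError("landmark set does not follow the requested schema")
    col_axis = columellar_axis(landmarks)
    vrl = vertical_reference_line(landmarks)
    left = np.empty(9)
    right = np.empty(9)
    for i in range(1, 10):
        spec = MEASUREMENT_TABLE[i]
        left[i - 1] = _measure_side(landmarks, spec, "left", col_axis, vrl)
        right[i - 1] = _measure_side(landmarks, spec, "right", col_axis, vrl)
    if np.any(right == 0) or np.any(left == 0):
        raise ValueError("degenerate anatomy: zero-valued measurement")
    return GeometryFeatures(f=left / right, left=left, right=right)


@dataclass
class FeatureScaler:
    """Per-feature training extrema for min-max normalization to [0, 1]."""

    gf_min: np.ndarray
    gf_max: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.gf_min > self.gf_max):
            raise ValueError("gf_min must be <= gf_max")


def fit_feature_scaler(training_features: list[GeometryFeatures]) -> FeatureScaler:
    if not training_features:
        raise ValueError("cannot fit a feature scaler on an empty training set")
    stack = np.stack([gf.f for gf in training_features])
    return FeatureScaler(gf_min=stack.min(axis=0), gf_max=stack.max(axis=0))


def normalize_features(features: GeometryFeatures, scaler: FeatureScaler) -> np.ndarray:
    """Min-max normalize the nine features with training extrema.

    Features whose training range is degenerate (max == min) map to 0:
    a constant feature carries no information.  Values outside the
    training range are NOT clamped.
    """
    rng = scaler.gf_max - scaler.gf_min
    out = np.zeros(9)
    ok = rng > 0
    out[ok] = (features.f[ok] - scaler.gf_min[ok]) / rng[ok]
    return out


def features_to_frame(items: list[tuple[str, GeometryFeatures]]) -> pd.DataFrame:
    """Tabulate features as one row per image: image_id, f_g_1..f_g_9."""
    rows = [
        {"image_id": image_id, **{f"f_g_{i}": gf.f[i - 1] for i in range(1, 10)}}
        for image_id, gf in items
    ]
    return pd.DataFrame(rows)
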
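"""Explanation overlay: which nasal-base region disrupts symmetry.

Two complementary saliency sources are intersected: per-tile occlusion
importance of the trained fusion model (replace one tile with the white
masking baseline and measure the change in the predicted symmetry) and
the geometry features whose ratio lies far from 1.  Each flagged
feature contributes the anatomical region spanned by its defining
landmarks on both sides — asymmetry is a property of the pair — and the
union of those regions is intersected with the image area of the
important tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage.morphology import dilation, disk

from .geometry import MEASUREMENT_TABLE, GeometryFeatures
from .schema import LandmarkSet
from .geometry import columellar_axis
from .symmetry import CombinedModel, SymmetrySample, _axis_split

__all__ = [
    "HeatmapOverlay",
    "FEATURE_REGIONS",
    "tile_importance",
    "feature_distance_flags",
    "intersect_and_render",
]

#: Landmarks spanning the anatomical region of each geometry feature
#: (both sides; derived from the measurement table's defining points).
FEATURE_REGIONS: dict[int, tuple[str, ...]] = {
    i: tuple(spec["left"]) + tuple(spec["right"])
    for i, spec in MEASUREMENT_TABLE.items()
}
# axis-distance measurements need the midline points to span an area
for _i in (2, 3, 4, 5, 6):
    FEATURE_REGIONS[_i] = FEATURE_REGIONS[_i] + ("pronasale", "subnasale")


@dataclass
class HeatmapOverlay:
    tile_importance: np.ndarray        # (4,), sums to 1 when nonzero
    feature_flags: np.ndarray          # (9,) bool
    region_polygons: dict[int, np.ndarray]
    combined_mask: np.ndarray          # (H, W) bool
    rendering: np.ndarray              # (H, W, 4) uint8 RGBA


def tile_importance(model: CombinedModel, sample: SymmetrySample) -> np.ndarray:
    """Occlusion importance of each tile: absolute change of the predicted
    symmetry when that tile is replaced by the white masking baseline;
    normalized to sum 1 when any importance is nonzero."""
    if model.pixel_scaler is None:
        raise ValueError("model is not trained")
    base = model.predict([sample])[0]
    imps = np.zeros(4)
    for k in range(4):
        tiles = sample.tiles.copy()
        tiles[k] = 255
        occluded = SymmetrySample(image_id=sample.image_id, tiles=tiles,
                                  features=sample.features,
                                  ssim_target=sample.ssim_target)
        imps[k] = abs(base - model.predict([occluded])[0])
    total = imps.sum()
    return imps / total if total > 0 else imps


def feature_distance_flags(features: GeometryFeatures,
                           threshold: float = 0.1) -> np.ndarray:
    """Flag features whose left/right ratio is far from perfect symmetry:
    |f_i - 1| > threshold."""
    return np.abs(features.f - 1.0) > threshold


def _region_mask(landmarks: LandmarkSet, names: tuple[str, ...],
                 shape: tuple[int, int], margin: int) -> np.ndarray:
    pts = np.stack([landmarks[n] for n in names])
    h, w = shape
    if len(np.unique(pts, axis=0)) < 3:
        jitter = np.array([[0, 0], [0.5, 0], [0, 0.5]])
        pts = np.vstack([pts, pts[:1] + jitter[1:]])
    hull = ConvexHull(pts, qhull_options="QJ")
    verts = pts[hull.vertices]
    X, Y = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    mask = np.ones((h, w), dtype=bool)
    cx, cy = verts.mean(axis=0)
    for i in range(len(verts)):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % len(verts)]
        val = (bx - ax) * (Y - ay) - (by - ay) * (X - ax)
        ref = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        mask &= (val * np.sign(ref if ref != 0 else 1.0)) >= 0
    if margin > 0:
        mask = dilation(mask, disk(margin))
    return mask


def _tile_area_mask(landmarks: LandmarkSet, importance: np.ndarray,
                    shape: tuple[int, int], quantile: float) -> np.ndarray:
    h, w = shape
    axis = columellar_axis(landmarks)
    l, r = _axis_split(np.empty((h, w, 3), dtype=np.uint8), axis)
    mid = h // 2
    spans = [((0, mid), (0, l)), ((0, mid), (r, w)),
             ((mid, h), (0, l)), ((mid, h), (r, w))]
    cutoff = np.quantile(importance, quantile)
    mask = np.zeros((h, w), dtype=bool)
    for k, ((y0, y1), (x0, x1)) in enumerate(spans):
        if importance[k] >= cutoff and importance[k] > 0:
            mask[y0:y1, x0:x1] = True
    return mask



def intersect_and_render(
    importance: np.ndarray,
    flags: np.ndarray,
    landmarks: LandmarkSet,
    image: np.ndarray,
    margin: int = 5,
    tile_quantile: float = 0.5,
) -> HeatmapOverlay:
    """Combine tile importance and flagged-feature regions into a saliency
    mask over the (standardized) crop and render a translucent overlay."""
    h, w = image.shape[:2]
    regions: dict[int, np.ndarray] = {}
    union = np.zeros((h, w), dtype=bool)
    for i in range(1, 10):
        if flags[i - 1]:
            m = _region_mask(landmarks, FEATURE_REGIONS[i], (h, w), margin)
            regions[i] = m
            union |= m
    tile_mask = _tile_area_mask(landmarks, importance, (h, w), tile_quantile)
    combined = union & tile_mask
    overlay = np.zeros((h, w, 4), dtype=np.uint8)
    overlay[..., :3] = image
    overlay[..., 3] = 255
    red = np.array([220, 30, 30], dtype=float)
    alpha = 0.45
    blended = image.astype(float)
    blended[combined] = (1 - alpha) * blended[combined] + alpha * red
    overlay[..., :3] = np.clip(np.round(blended), 0, 255).astype(np.uint8)
    return HeatmapOverlay(
        tile_importance=np.asarray(importance, dtype=float),
        feature_flags=np.asarray(flags, dtype=bool),
        region_polygons=regions,
        combined_mask=combined,
        rendering=overlay,
    )
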
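"""Keypoint-aware augmentation: color jitter, flipping, shifting,
rotating and scaling, 25 augmented copies per input by default.

Geometric transforms move the image and its 18 landmarks with the same
affine map and recompute the ground-truth box from the transformed
landmarks.  A horizontal flip additionally swaps left/right landmark
labels, because mirroring turns a left alare into a right alare; the
geometry-ratio features of a flipped sample are therefore the
elementwise reciprocals of the original ones.  Landmarks pushed outside
the frame are clipped and flagged rather than dropped, keeping batch
shapes fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .boxes import ground_truth_box
from .sample import AnnotatedImage
from .schema import DEFAULT_SCHEMA, LandmarkSchema

__all__ = ["AugmentConfig", "apply_affine", "horizontal_flip",
           "color_jitter", "augment_batch"]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation ranges.

    Magnitudes default to mild values that preserve anatomy: rotation
    +/-15 degrees, shift +/-10% of the frame, scale in [0.9, 1.1], and
    brightness/contrast/saturation jitter of +/-20%.
    """

    flip_prob: float = 0.5
    rotation_range: float = 15.0
    shift_range: float = 0.10
    scale_range: tuple[float, float] = (0.9, 1.1)
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    samples_per_image: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_image < 1:
            raise ValueError("samples_per_image must be >= 1")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must be a probability")


def apply_affine(sample: AnnotatedImage, transform: AffineTransform) -> AnnotatedImage:
    """Warp image and landmarks with the same (invertible) affine map."""
    if abs(np.linalg.det(transform.params[:2, :2])) < 1e-12:
        raise ValueError("singular affine transform")
    h, w = sample.image.shape[:2]
    if np.allclose(transform.params, np.eye(3)):
        return AnnotatedImage(image=sample.image.copy(),
                              landmarks=sample.landmarks.with_points(
                                  sample.landmarks.points.copy()),
                              box=sample.box)
    img = warp(sample.image.astype(float), transform.inverse, mode="edge",
               preserve_range=True)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    pts = transform(sample.landmarks.points)
    oof = ((pts[:, 0] < 0) | (pts[:, 0] >= w) | (pts[:, 1] < 0) | (pts[:, 1] >= h))
    pts_clipped = np.column_stack([np.clip(pts[:, 0], 0, w - 1e-6),
                                   np.clip(pts[:, 1], 0, h - 1e-6)])
    lms = sample.landmarks.with_points(pts_clipped, out_of_frame=oof)
    out = AnnotatedImage(image=img, landmarks=lms)
    return out.with_box() if sample.box is not None else out


def horizontal_flip(sample: AnnotatedImage,
                    schema: LandmarkSchema = DEFAULT_SCHEMA) -> AnnotatedImage:
    """Mirror about the vertical centerline, swapping left/right labels."""
    h, w = sample.image.shape[:2]
    img = np.ascontiguousarray(sample.image[:, ::-1])
    pts = sample.landmarks.points.copy()
    pts[:, 0] = w - pts[:, 0]
    order = [schema.index(schema.lr_pairs.get(n, n)) for n in schema.names]
    pts = pts[order]
    oof = sample.landmarks.out_of_frame[order]
    lms = sample.landmarks.with_points(pts, out_of_frame=oof)
    out = AnnotatedImage(image=img, landmarks=lms)
    return out.with_box() if sample.box is not None else out


def color_jitter(image: np.ndarray, brightness: float, contrast: float,
                 saturation: float) -> np.ndarray:
    """Multiplicative brightness, mean-anchored contrast, and
    gray-interpolated saturation adjustment; landmarks are untouched."""
    img = image.astype(float)
    img = img * (1.0 + brightness)
    mean = img.mean()
    img = (img - mean) * (1.0 + contrast) + mean
    gray = img.mean(axis=2, keepdims=True)
    img = gray + (img - gray) * (1.0 + saturation)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def augment_batch(sample: AnnotatedImage,
                  config: AugmentConfig = AugmentConfig()) -> list[AnnotatedImage]:
    """Produce exactly ``samples_per_image`` augmented copies, seeded."""
    rng = np.random.default_rng(config.seed)
    h, w = sample.image.shape[:2]
    cx, cy = w / 2, h / 2
    out = []
    for k in range(config.samples_per_image):
        s = sample
        if rng.uniform() < config.flip_prob:
            s = horizontal_flip(s)
        theta = np.radians(rng.uniform(-config.rotation_range, config.rotation_range))
        scale = rng.uniform(*config.scale_range)
        dx = rng.uniform(-config.shift_range, config.shift_range) * w
        dy = rng.uniform(-config.shift_range, config.shift_range) * h
        center = AffineTransform(translation=(-cx, -cy))
        core = AffineTransform(scale=(scale, scale), rotation=theta)
        back = AffineTransform(translation=(cx + dx, cy + dy))
        tf = AffineTransform(matrix=back.params @ core.params @ center.params)
        s = apply_affine(s, tf)
        img = color_jitter(
            s.image,
            rng.uniform(-config.brightness, config.brightness),
            rng.uniform(-config.contrast, config.contrast),
            rng.uniform(-config.saturation, config.saturation),
        )
        s = AnnotatedImage(image=img, landmarks=s.landmarks, box=s.box)
        s.landmarks.image_id = f"{sample.image_id}_aug{k:02d}"
        out.append(s)
    return out
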
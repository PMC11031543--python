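"""The unit of data flowing through the framework: image + annotation."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .boxes import BoundingBox, ground_truth_box
from .schema import LandmarkSet, read_annotation, write_annotation

__all__ = ["AnnotatedImage", "load_sample", "save_sample"]


@dataclass
class AnnotatedImage:
    """An RGB image with its 18-landmark annotation and (optionally) the
    nasal-base bounding box."""

    image: np.ndarray  # (H, W, 3) uint8
    landmarks: LandmarkSet
    box: BoundingBox | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
            raise ValueError("image must be (H, W, 3) uint8")
        self.image = img

    @property
    def image_id(self) -> str:
        return self.landmarks.image_id

    def with_box(self, pad: float = 0.15) -> "AnnotatedImage":
        return replace(self, box=ground_truth_box(self.landmarks, pad=pad))


def save_sample(sample: AnnotatedImage, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a PNG + annotation-JSON pair named after the image id."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{sample.image_id}.png"
    ann_path = out_dir / f"{sample.image_id}.json"
    Image.fromarray(sample.image).save(img_path)
    write_annotation(ann_path, sample.landmarks, image_path=img_path.name)
    return img_path, ann_path


def load_sample(img_path: str | Path, ann_path: str | Path | None = None) -> AnnotatedImage:
    img_path = Path(img_path)
    if ann_path is None:
        ann_path = img_path.with_suffix(".json")
    img = np.asarray(Image.open(img_path).convert("RGB"))
    lms = read_annotation(ann_path)
    lms.image_id = img_path.stem
    return AnnotatedImage(image=img, landmarks=lms)
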
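"""Crop-based landmark regression and its evaluation metrics.

The prediction module of the hybrid pipeline: the detected nasal-base
box is cropped out of the image, landmark annotations are re-expressed
in crop coordinates, and a small CNN regresses all 18 landmark
positions (36 reals, normalized to the crop) with an MAE loss.

Metrics follow the facial-alignment conventions: NME is the per-image
sum of Euclidean landmark errors divided by the square root of the
ground-truth box area, averaged over images; MAPE is the mean per-image
summed Euclidean pixel error; MAE/RMSE are computed over flattened
coordinate residuals and PC is the Pearson correlation between
flattened predicted and true coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import _nn
from .boxes import BoundingBox, ground_truth_box
from .sample import AnnotatedImage
from .schema import LandmarkSet

__all__ = [
    "LandmarkMetrics",
    "RegressorConfig",
    "crop_and_reproject",
    "zoom_in",
    "zoom_out",
    "LandmarkRegressor",
    "train_regressor",
    "compute_metrics",
    "perturb_landmarks",
    "add_gaussian_noise",
]


def crop_and_reproject(sample: AnnotatedImage, box: BoundingBox,
                       out_size: int | None = None) -> AnnotatedImage:
    """Crop the image to ``box`` and re-express landmarks in crop pixels.

    With ``out_size`` the crop is resized to a square model input and the
    landmarks are scaled along.  Raises when the box leaves the image.
    """
    h, w = sample.image.shape[:2]
    x0, y0 = int(np.floor(box.x_min)), int(np.floor(box.y_min))
    x1, y1 = int(np.ceil(box.x_max)), int(np.ceil(box.y_max))
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError("crop box lies outside the image")
    crop = sample.image[y0:y1, x0:x1]
    pts = sample.landmarks.points - np.array([x0, y0], dtype=float)
    cw, ch = x1 - x0, y1 - y0
    if out_size is not None:
        fx, fy = out_size / cw, out_size / ch
        crop = np.clip(np.round(resize(crop.astype(float), (out_size, out_size, 3),
                                       anti_aliasing=True, preserve_range=True)),
                       0, 255).astype(np.uint8)
        pts = pts * np.array([fx, fy])
        cw = ch = out_size
    lms = sample.landmarks.with_points(pts, frame="crop", frame_size=(cw, ch))
    return AnnotatedImage(image=np.ascontiguousarray(crop), landmarks=lms)


def jitter_box(box: BoundingBox, rng: np.random.Generator,
               center_frac: float = 0.07, scale_frac: float = 0.15,
               frame_size: tuple[int, int] | None = None) -> BoundingBox:
    """Randomly perturb a box's center and scale.

    Used to augment regressor training crops so the model tolerates the
    localization jitter of a real detector instead of assuming a
    perfectly registered crop."""
    cx, cy = box.center
    w = box.width * (1 + rng.uniform(-scale_frac, scale_frac))
    h = box.height * (1 + rng.uniform(-scale_frac, scale_frac))
    cx += rng.uniform(-center_frac, center_frac) * box.width
    cy += rng.uniform(-center_frac, center_frac) * box.height
    x0, y0 = cx - w / 2, cy - h / 2
    x1, y1 = cx + w / 2, cy + h / 2
    if frame_size is not None:
        fw, fh = frame_size
        x0, y0 = max(0.0, x0), max(0.0, y0)
        x1, y1 = min(float(fw), x1), min(float(fh), y1)
    return BoundingBox(x0, y0, x1, y1)


def zoom_in(points: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Map whole-image coordinates into the normalized [0,1]^2 crop frame
    of ``box`` so they are comparable with crop-scale predictions."""
    if box.width <= 0 or box.height <= 0:
        raise ValueError("degenerate box")
    pts = np.asarray(points, dtype=float)
    return (pts - [box.x_min, box.y_min]) / [box.width, box.height]


def zoom_out(points: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Exact inverse of :func:`zoom_in`: normalized crop coordinates back
    to the whole-image frame."""
    if box.width <= 0 or box.height <= 0:
        raise ValueError("degenerate box")
    pts = np.asarray(points, dtype=float)
    return pts * [box.width, box.height] + [box.x_min, box.y_min]


@dataclass(frozen=True)
class RegressorConfig:
    """Architecture and optimization settings of the landmark regressor."""

    input_size: int = 64
    channels: tuple[int, ...] = (16, 32, 64, 64)
    hidden: int = 256
    leaky_slope: float = 0.1
    batch_size: int = 32
    lr: float = 1e-3
    schedule: str = "step"
    epochs: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.leaky_slope < 1:
            raise ValueError("leaky slope must be in (0, 1)")


class LandmarkRegressor:
    """Small CNN mapping a square grayscale crop to 36 normalized
    landmark coordinates."""

    def __init__(self, config: RegressorConfig = RegressorConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list[_nn.Layer] = []
        cin = 1
        size = config.input_size
        for c in config.channels:
            layers += [_nn.Conv2d(cin, c, 3, stride=2, rng=rng),
                       _nn.LeakyReLU(config.leaky_slope)]
            cin = c
            size //= 2
        layers += [_nn.Flatten(),
                   _nn.Dense(cin * size * size, config.hidden, rng=rng),
                   _nn.LeakyReLU(config.leaky_slope),
                   _nn.Dense(config.hidden, 36, rng=rng)]
        self.net = _nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def _to_input(self, images: np.ndarray) -> np.ndarray:
        x = images.astype(np.float32).mean(axis=3) / np.float32(255.0) - np.float32(0.5)
        return x[:, None]

    def predict(self, crops: list[AnnotatedImage] | np.ndarray) -> np.ndarray:
        """Normalized (N, 18, 2) landmark predictions for square crops."""
        if isinstance(crops, list):
            images = np.stack([c.image for c in crops])
        else:
            images = crops
        out = self.net.forward(self._to_input(images))
        return out.reshape(-1, 18, 2)

    def predict_landmarks(self, sample: AnnotatedImage, box: BoundingBox) -> LandmarkSet:
        """End-of-pipeline prediction: crop ``sample`` to ``box``, regress,
        zoom the result back out to whole-image coordinates."""
        crop = crop_and_reproject(sample, box, out_size=self.config.input_size)
        norm = self.predict([crop])[0]
        cb = BoundingBox(np.floor(box.x_min), np.floor(box.y_min),
                         np.ceil(box.x_max), np.ceil(box.y_max))
        pts = zoom_out(norm, cb)
        return sample.landmarks.with_points(pts)

    def state_arrays(self) -> list[np.ndarray]:
        return [p["value"].copy() for p in self.params()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.params(), arrays):
            p["value"][...] = a

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i}": p["value"] for i, p in enumerate(self.params())})
        path.with_suffix(".json").write_text(json.dumps(self.config.__dict__, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LandmarkRegressor":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        meta["channels"] = tuple(meta["channels"])
        reg = cls(RegressorConfig(**meta))
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(reg.params()):
            p["value"][...] = data[f"p{i}"]
        return reg


def train_regressor(
    crops: list[AnnotatedImage],
    config: RegressorConfig = RegressorConfig(),
    val_crops: list[AnnotatedImage] | None = None,
    verbose: bool = False,
) -> tuple[LandmarkRegressor, dict]:
    """Train the crop-to-landmarks CNN with an MAE loss.

    Targets are landmark coordinates normalized to the crop.  The output
    bias is initialized to the mean training landmark position, so the
    net starts from the population-average face and learns residuals.
    Parameters with the best validation loss are kept.
    """
    if not crops:
        raise ValueError("empty training set")
    if val_crops is None:
        n_val = max(1, len(crops) // 5)
        val_crops, crops = crops[-n_val:], crops[:-n_val]

    def prep(cs: list[AnnotatedImage]) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([c.image for c in cs])
        Y = np.stack([
            c.landmarks.points / np.array(c.landmarks.frame_size, dtype=float)
            for c in cs
        ]).reshape(len(cs), 36).astype(np.float32)
        return X, Y

    X, Y = prep(crops)
    Xv, Yv = prep(val_crops)
    reg = LandmarkRegressor(config)
    # bias of the output layer -> mean landmark constellation
    reg.net.layers[-1].b[...] = Y.mean(axis=0)
    Xin, Xvin = reg._to_input(X), reg._to_input(Xv)

    opt = _nn.Adam(reg.params(), lr=config.lr)
    sched = _nn.lr_schedule(config.schedule, config.lr, config.epochs,
                            step_every=max(10, config.epochs // 3))
    rng = np.random.default_rng(config.seed)
    best = (np.inf, reg.state_arrays())
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        opt.lr = sched(epoch)
        order = rng.permutation(len(crops))
        ep_loss = 0.0
        for k in range(0, len(order), config.batch_size):
            idx = order[k:k + config.batch_size]
            out = reg.net.forward(Xin[idx])
            loss, grad = _nn.mae_loss(out, Y[idx])
            reg.net.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
        val_loss, _ = _nn.mae_loss(reg.net.forward(Xvin), Yv)
        history["train_loss"].append(ep_loss / len(crops))
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, reg.state_arrays())
        if verbose:
            print(f"epoch {epoch:3d} train {history['train_loss'][-1]:.5f} "
                  f"val {val_loss:.5f}")
    reg.set_state(best[1])
    history["best_val_loss"] = best[0]
    return reg, history


@dataclass
class LandmarkMetrics:
    mae: float
    nme: float
    mape: float
    rmse: float
    pc: float
    n: int
    m: int = 18


def compute_metrics(
    pred: list[LandmarkSet],
    truth: list[LandmarkSet],
    boxes: list[BoundingBox],
) -> LandmarkMetrics:
    """Landmark-regression metrics over aligned prediction/truth lists.

    ``boxes`` supplies each image's ground-truth box; its sqrt-area d_j
    normalizes the per-image summed landmark error (NME).
    """
    if not (len(pred) == len(truth) == len(boxes)):
        raise ValueError("pred, truth and boxes must have equal lengths")
    per_image_sums = []
    nmes = []
    res_p, res_t = [], []
    for pj, tj, bj in zip(pred, truth, boxes):
        err = np.linalg.norm(pj.points - tj.points, axis=1)
        d_j = np.sqrt(bj.width * bj.height)
        per_image_sums.append(err.sum())
        nmes.append(err.sum() / d_j)
        res_p.append(pj.points.ravel())
        res_t.append(tj.points.ravel())
    res_p = np.concatenate(res_p)
    res_t = np.concatenate(res_t)
    diff = res_p - res_t
    pc = float(np.corrcoef(res_p, res_t)[0, 1]) if len(res_p) > 1 else 1.0
    return LandmarkMetrics(
        mae=float(np.abs(diff).mean()),
        nme=float(np.mean(nmes)),
        mape=float(np.mean(per_image_sums)),
        rmse=float(np.sqrt((diff ** 2).mean())),
        pc=pc,
        n=len(pred),
    )


def perturb_landmarks(landmarks: LandmarkSet, k_range: tuple[int, int] = (3, 7),
                      shift_range_px: tuple[int, int] = (1, 5),
                      seed: int = 0) -> LandmarkSet:
    """Corrupt a landmark set the way annotation errors do: move k
    randomly chosen landmarks by an integer 1-5 px step in one of the four
    axis directions (top, bottom, left, right)."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(k_range[0], k_range[1] + 1))
    idx = rng.choice(18, size=min(k, 18), replace=False)
    pts = landmarks.points.copy()
    dirs = np.array([(0, -1), (0, 1), (-1, 0), (1, 0)], dtype=float)
    for i in idx:
        step = int(rng.integers(shift_range_px[0], shift_range_px[1] + 1))
        pts[i] += dirs[rng.integers(0, 4)] * step
    return landmarks.with_points(pts)


def add_gaussian_noise(image: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Additive i.i.d. Gaussian pixel noise, clipped to [0, 255]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noisy = image.astype(float) + rng.normal(0, sigma, image.shape)
    return np.clip(np.round(noisy), 0, 255).astype(np.uint8)
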
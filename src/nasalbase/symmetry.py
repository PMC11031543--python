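"""SSIM-supervised symmetry scoring of the nasal base.

Preprocessing standardizes each annotated image (head roll removed by
rotating the columellar axis vertical, cropped to the nasal-base box,
resized to a canonical square), masks everything outside the landmark
hull with white, splits the crop at the columellar axis, and builds a
four-tile (left/right x upper/lower) representation.

The symmetry ground truth is the structural similarity (SSIM) between
the left half and the mirrored right half of the masked crop.  A small
CNN over the tile stack and an MLP over the nine normalized geometry
features are fused by concatenating their last hidden layers into one
regression head trained with an MAE loss against that SSIM target.
Continuous scores map to five ordinal symmetry categories for
comparison with expert ratings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull
from skimage.color import rgb2gray
from skimage.metrics import structural_similarity
from skimage.morphology import dilation, disk
from skimage.transform import AffineTransform, resize, warp

from . import _nn
from .boxes import BoundingBox, ground_truth_box
from .geometry import (FeatureScaler, GeometryFeatures, columellar_axis,
                       compute_geometry_features, fit_feature_scaler,
                       normalize_features)
from .sample import AnnotatedImage
from .schema import Axis

__all__ = [
    "SymmetrySample",
    "PixelScaler",
    "RankScale",
    "standardize",
    "mask_roi",
    "split_halves",
    "ssim_symmetry",
    "ssim_ground_truth",
    "make_tiles",
    "fit_pixel_scaler",
    "normalize_pixels",
    "CombinedModel",
    "CombinedConfig",
    "train_combined",
    "prepare_symmetry_sample",
    "score_to_rank",
    "match_ratings",
]

_WHITE = np.array([255, 255, 255], dtype=np.uint8)


# ---------------------------------------------------------------------------
# preprocessing


def standardize(sample: AnnotatedImage, out_size: int = 128,
                pad: float = 0.15) -> AnnotatedImage:
    """Remove head roll and crop to the canonical nasal-base frame.

    Rotates about the subnasale so the columellar axis points straight
    up, crops to the (padded) landmark box and resizes to a square of
    ``out_size``; landmarks are transformed consistently.
    """
    from .landmarks import crop_and_reproject  # deferred: sibling module

    axis = columellar_axis(sample.landmarks)
    d = axis.direction
    phi = np.arctan2(-d[0], -d[1])  # rotation taking d to (0, -1)
    c = sample.landmarks["subnasale"]
    R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    pts = (sample.landmarks.points - c) @ R.T + c
    tf = AffineTransform(matrix=np.array([
        [R[0, 0], R[0, 1], c[0] - R[0, 0] * c[0] - R[0, 1] * c[1]],
        [R[1, 0], R[1, 1], c[1] - R[1, 0] * c[0] - R[1, 1] * c[1]],
        [0, 0, 1],
    ]))
    if abs(phi) > 1e-12:
        img = warp(sample.image.astype(float), tf.inverse, mode="edge",
                   preserve_range=True)
        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    else:
        img = sample.image
    h, w = img.shape[:2]
    lms = sample.landmarks.with_points(pts, frame_size=(w, h))
    rotated = AnnotatedImage(image=img, landmarks=lms)
    box = ground_truth_box(lms, pad=pad)
    # grow the box to a square so the resize is isotropic and geometry
    # ratios survive standardization unchanged
    side = max(box.width, box.height)
    cx_, cy_ = box.center
    x0 = min(max(0.0, cx_ - side / 2), max(0.0, w - side))
    y0 = min(max(0.0, cy_ - side / 2), max(0.0, h - side))
    square = BoundingBox(x0, y0, min(float(w), x0 + side), min(float(h), y0 + side))
    return crop_and_reproject(rotated, square, out_size=out_size)


def vertical_axis_of(sample: AnnotatedImage) -> Axis:
    """Columellar axis of a standardized sample (vertical by construction)."""
    return columellar_axis(sample.landmarks)


def mask_roi(sample: AnnotatedImage, margin: int = 6) -> np.ndarray:
    """White-mask everything outside the dilated convex hull of the
    landmarks, separating the nasal base from the background."""
    pts = sample.landmarks.points
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # collinear landmarks
        raise ValueError("degenerate landmark hull") from exc
    verts = pts[hull.vertices]
    h, w = sample.image.shape[:2]
    # half-plane rasterization at pixel centers: sub-pixel exact, and a
    # mirror-symmetric hull yields a mirror-symmetric mask
    X, Y = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    mask = np.ones((h, w), dtype=bool)
    cx_, cy_ = verts.mean(axis=0)
    for i in range(len(verts)):
        ax_, ay = verts[i]
        bx, by = verts[(i + 1) % len(verts)]
        edge = lambda px, py: (bx - ax_) * (py - ay) - (by - ay) * (px - ax_)
        sign = 1.0 if edge(cx_, cy_) >= 0 else -1.0
        mask &= sign * edge(X, Y) >= 0
    if margin > 0:
        mask = dilation(mask, disk(margin))
    out = sample.image.copy()
    out[~mask] = _WHITE
    return out


def _axis_split(image: np.ndarray, axis: Axis) -> tuple[int, int]:
    """Column ranges induced by the axis: left ends at ``l``, right starts
    at ``r``.  When the axis runs along a pixel boundary the split is
    clean (r == l); when it passes through a pixel's interior that axis
    column belongs to neither half (r == l + 1)."""
    x = float(axis.point[0])
    w = image.shape[1]
    if not 1.0 <= x <= w - 1.0:
        raise ValueError("columellar axis lies outside the image")
    b = round(x)
    if abs(x - b) <= 0.25:  # boundary split between columns b-1 and b
        return b, b
    c = int(np.floor(x))
    return c, c + 1


def split_halves(image: np.ndarray, axis: Axis) -> tuple[np.ndarray, np.ndarray]:
    """Split a standardized image at the columellar axis.

    A pixel column containing the axis belongs to neither half; the
    halves are white-padded on their outer edge to a common width.
    """
    l, r = _axis_split(image, axis)
    left = image[:, :l]
    right = image[:, r:]
    width = max(left.shape[1], right.shape[1])

    def pad_to(img: np.ndarray, side: str) -> np.ndarray:
        deficit = width - img.shape[1]
        if deficit == 0:
            return img
        pad = np.broadcast_to(_WHITE, (img.shape[0], deficit, 3)).astype(np.uint8)
        return np.concatenate([pad, img] if side == "left" else [img, pad], axis=1)

    return pad_to(left, "left"), pad_to(right, "right")


def ssim_symmetry(image: np.ndarray, axis: Axis, trim_white: bool = True) -> float:
    """SSIM between the left half and the mirrored right half (grayscale,
    Gaussian window sigma 1.5, K1=0.01/K2=0.03, dynamic range 255),
    clamped to [0, 1].  1.0 means a perfectly mirror-symmetric nasal base.

    With ``trim_white`` the border that is white in both halves (the
    masked background) is cut away first, so the score reflects the
    nasal base rather than the shared blank margin.
    """
    left, right = split_halves(image, axis)
    gl = rgb2gray(left) * 255.0
    gr = rgb2gray(right[:, ::-1]) * 255.0
    if trim_white:
        nz = (gl < 250) | (gr < 250)
        if nz.any():
            ys, xs = np.nonzero(nz)
            y0 = max(0, ys.min() - 3)
            x0 = max(0, xs.min() - 3)
            y1 = min(gl.shape[0], ys.max() + 4)
            x1 = min(gl.shape[1], xs.max() + 4)
            if min(y1 - y0, x1 - x0) >= 11:
                gl, gr = gl[y0:y1, x0:x1], gr[y0:y1, x0:x1]
    if min(gl.shape) < 11:
        raise ValueError("halves smaller than the SSIM window")
    val = structural_similarity(
        gl, gr, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=255.0,
    )
    return float(np.clip(val, 0.0, 1.0))


def ssim_ground_truth(sample: AnnotatedImage, out_size: int = 128,
                      margin: int = 6) -> float:
    """Standardize, mask and score one annotated image in a single call."""
    std = standardize(sample, out_size=out_size)
    masked = mask_roi(std, margin=margin)
    return ssim_symmetry(masked, vertical_axis_of(std))


def make_tiles(image: np.ndarray, axis: Axis, tile_size: int = 32) -> np.ndarray:
    """Four-tile representation of the masked crop: the 2x2 grid given by
    the columellar-axis column and the horizontal midline, each tile
    resized to ``tile_size``; order (LU, RU, LL, RL)."""
    l, r = _axis_split(image, axis)
    h = image.shape[0]
    mid = h // 2
    quads = [image[:mid, :l], image[:mid, r:],
             image[mid:, :l], image[mid:, r:]]
    tiles = [
        np.clip(np.round(resize(q.astype(float), (tile_size, tile_size, 3),
                                anti_aliasing=True, preserve_range=True)),
                0, 255).astype(np.uint8)
        for q in quads
    ]
    return np.stack(tiles)


# ---------------------------------------------------------------------------
# pixel and feature normalizations


@dataclass
class PixelScaler:
    """Per-color-channel mean/std of the training tiles (z-score units)."""

    mean: np.ndarray  # (3,)
    std: np.ndarray   # (3,)

    def __post_init__(self) -> None:
        if np.any(self.std <= 0):
            raise ValueError("constant channel: zero std")


def fit_pixel_scaler(tile_stacks: list[np.ndarray] | np.ndarray) -> PixelScaler:
    data = np.asarray(tile_stacks, dtype=float)
    mean = data.reshape(-1, 3).mean(axis=0)
    std = data.reshape(-1, 3).std(axis=0)
    return PixelScaler(mean=mean, std=std)


def normalize_pixels(tiles: np.ndarray, scaler: PixelScaler) -> np.ndarray:
    """Per-channel z-score with training-set statistics."""
    return (np.asarray(tiles, dtype=float) - scaler.mean) / scaler.std


# ---------------------------------------------------------------------------
# the combined CNN + MLP regressor


@dataclass
class SymmetrySample:
    """One training/evaluation unit for the combined model."""

    image_id: str
    tiles: np.ndarray          # (4, t, t, 3) uint8
    features: GeometryFeatures
    ssim_target: float

    def __post_init__(self) -> None:
        if self.tiles.shape[0] != 4:
            raise ValueError("expected exactly 4 tiles")
        if not 0.0 <= self.ssim_target <= 1.0:
            raise ValueError("ssim target must lie in [0, 1]")


def prepare_symmetry_sample(sample: AnnotatedImage, out_size: int = 128,
                            margin: int = 6, tile_size: int = 32) -> SymmetrySample:
    """Full preprocessing of one annotated image into a SymmetrySample."""
    std = standardize(sample, out_size=out_size)
    axis = vertical_axis_of(std)
    masked = mask_roi(std, margin=margin)
    return SymmetrySample(
        image_id=sample.image_id,
        tiles=make_tiles(masked, axis, tile_size=tile_size),
        features=compute_geometry_features(std.landmarks),
        ssim_target=ssim_symmetry(masked, axis),
    )


@dataclass(frozen=True)
class CombinedConfig:
    tile_size: int = 32
    cnn_channels: tuple[int, ...] = (16, 32)
    cnn_hidden: int = 48
    mlp_hidden: tuple[int, ...] = (32, 32)
    head_hidden: int = 32
    leaky_slope: float = 0.1
    batch_size: int = 8
    lr: float = 1e-3
    epochs: int = 60
    seed: int = 0


class CombinedModel:
    """Tile-stack CNN and geometry-feature MLP fused at the last hidden
    layer into a single symmetry-score output."""

    def __init__(self, config: CombinedConfig = CombinedConfig()):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        layers: list[_nn.Layer] = []
        cin = 12  # 4 tiles x 3 color channels
        size = c.tile_size
        for ch in c.cnn_channels:
            layers += [_nn.Conv2d(cin, ch, 3, stride=2, rng=rng),
                       _nn.LeakyReLU(c.leaky_slope)]
            cin = ch
            size //= 2
        layers += [_nn.Flatten(),
                   _nn.Dense(cin * size * size, c.cnn_hidden, rng=rng),
                   _nn.LeakyReLU(c.leaky_slope)]
        self.cnn = _nn.Sequential(*layers)
        mlp_layers: list[_nn.Layer] = []
        nin = 9
        for nh in c.mlp_hidden:
            mlp_layers += [_nn.Dense(nin, nh, rng=rng), _nn.LeakyReLU(c.leaky_slope)]
            nin = nh
        self.mlp = _nn.Sequential(*mlp_layers)
        self.head = _nn.Sequential(
            _nn.Dense(c.cnn_hidden + nin, c.head_hidden, rng=rng),
            _nn.LeakyReLU(c.leaky_slope),
            _nn.Dense(c.head_hidden, 1, rng=rng),
        )
        self.pixel_scaler: PixelScaler | None = None
        self.feature_scaler: FeatureScaler | None = None

    def params(self):
        return self.cnn.params() + self.mlp.params() + self.head.params()

    def forward(self, tiles_z: np.ndarray, ngf: np.ndarray) -> np.ndarray:
        """tiles_z: (N, 4, t, t, 3) z-scored; ngf: (N, 9) normalized."""
        n = tiles_z.shape[0]
        x = tiles_z.transpose(0, 1, 4, 2, 3).reshape(
            n, 12, self.config.tile_size, self.config.tile_size
        ).astype(np.float32)
        self._h_img = self.cnn.forward(x)
        self._h_ft = self.mlp.forward(ngf.astype(np.float32))
        fused = np.concatenate([self._h_img, self._h_ft], axis=1)
        return self.head.forward(fused)[:, 0]

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad[:, None].astype(np.float32))
        nc = self._h_img.shape[1]
        self.cnn.backward(g[:, :nc])
        self.mlp.backward(g[:, nc:])

    def predict(self, samples: list[SymmetrySample]) -> np.ndarray:
        """Symmetry scores for prepared samples (scalers must be fitted)."""
        if self.pixel_scaler is None or self.feature_scaler is None:
            raise ValueError("model scalers are not fitted; train first")
        tiles = np.stack([normalize_pixels(s.tiles, self.pixel_scaler)
                          for s in samples])
        ngf = np.stack([normalize_features(s.features, self.feature_scaler)
                        for s in samples])
        return self.forward(tiles, ngf)

    def state_arrays(self) -> list[np.ndarray]:
        return [p["value"].copy() for p in self.params()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.params(), arrays):
            p["value"][...] = a

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i}": p["value"] for i, p in enumerate(self.params())})
        meta = dict(self.config.__dict__)
        meta["pixel_scaler"] = {"mean": self.pixel_scaler.mean.tolist(),
                                "std": self.pixel_scaler.std.tolist()}
        meta["feature_scaler"] = {"gf_min": self.feature_scaler.gf_min.tolist(),
                                  "gf_max": self.feature_scaler.gf_max.tolist()}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CombinedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        ps, fs = meta.pop("pixel_scaler"), meta.pop("feature_scaler")
        for key in ("cnn_channels", "mlp_hidden"):
            meta[key] = tuple(meta[key])
        model = cls(CombinedConfig(**meta))
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.params()):
            p["value"][...] = data[f"p{i}"]
        model.pixel_scaler = PixelScaler(np.array(ps["mean"]), np.array(ps["std"]))
        model.feature_scaler = FeatureScaler(np.array(fs["gf_min"]),
                                             np.array(fs["gf_max"]))
        return model


def train_combined(
    samples: list[SymmetrySample],
    config: CombinedConfig = CombinedConfig(),
    val_samples: list[SymmetrySample] | None = None,
    verbose: bool = False,
) -> tuple[CombinedModel, dict]:
    """Train the fusion regressor against SSIM targets with an MAE loss.

    Pixel and feature scalers are fitted on the training set only; the
    checkpoint with the best validation MAE is kept.  Reported metrics
    (on validation) are MAE, RMSE and the Pearson correlation.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples")
    if val_samples is None:
        n_val = max(1, len(samples) // 5)
        val_samples, samples = samples[-n_val:], samples[:-n_val]

    model = CombinedModel(config)
    model.pixel_scaler = fit_pixel_scaler([s.tiles for s in samples])
    model.feature_scaler = fit_feature_scaler([s.features for s in samples])

    def prep(ss: list[SymmetrySample]):
        tiles = np.stack([normalize_pixels(s.tiles, model.pixel_scaler)
                          for s in ss]).astype(np.float32)
        ngf = np.stack([normalize_features(s.features, model.feature_scaler)
                        for s in ss]).astype(np.float32)
        y = np.array([s.ssim_target for s in ss], dtype=np.float32)
        return tiles, ngf, y

    T, F, Y = prep(samples)
    Tv, Fv, Yv = prep(val_samples)
    opt = _nn.Adam(model.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    best = (np.inf, model.state_arrays())
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        order = rng.permutation(len(samples))
        ep_loss = 0.0
        for k in range(0, len(order), config.batch_size):
            idx = order[k:k + config.batch_size]
            out = model.forward(T[idx], F[idx])
            loss, grad = _nn.mae_loss(out, Y[idx])
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
        val_pred = model.forward(Tv, Fv)
        val_loss = float(np.abs(val_pred - Yv).mean())
        history["train_loss"].append(ep_loss / len(samples))
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, model.state_arrays())
        if verbose:
            print(f"epoch {epoch:3d} train {history['train_loss'][-1]:.4f} "
                  f"val {val_loss:.4f}")
    model.set_state(best[1])
    val_pred = model.forward(Tv, Fv)
    history["best_val_loss"] = best[0]
    history["val_mae"] = float(np.abs(val_pred - Yv).mean())
    history["val_rmse"] = float(np.sqrt(((val_pred - Yv) ** 2).mean()))
    history["val_pc"] = float(np.corrcoef(val_pred, Yv)[0, 1])
    return model, history


# ---------------------------------------------------------------------------
# ordinal ranks and expert matching


@dataclass(frozen=True)
class RankScale:
    """Five ordinal symmetry categories partitioned by four thresholds on
    the symmetry score (the thresholds mirror expert practice and are
    deliberately configurable)."""

    labels: tuple[str, ...] = (
        "completely symmetric",
        "very symmetric",
        "slightly symmetric",
        "asymmetric",
        "completely asymmetric",
    )
    thresholds: tuple[float, ...] = (0.95, 0.85, 0.70, 0.50)

    def __post_init__(self) -> None:
        if len(self.labels) != 5 or len(self.thresholds) != 4:
            raise ValueError("need 5 categories and 4 thresholds")
        if list(self.thresholds) != sorted(self.thresholds, reverse=True):
            raise ValueError("thresholds must be strictly decreasing")


def score_to_rank(score: float, scale: RankScale = RankScale()) -> str:
    """Map a symmetry score in [0, 1] to its ordinal category."""
    for label, thr in zip(scale.labels, scale.thresholds):
        if score >= thr:
            return label
    return scale.labels[-1]


def match_ratings(pred_ranks: list[str], rater_ranks: list[str],
                  scale: RankScale = RankScale()) -> dict[str, float]:
    """Exact and fine agreement between two ordinal rank lists.

    Exact matching is the fraction of identical categories; fine
    matching additionally accepts being one ordinal category apart.
    """
    if len(pred_ranks) != len(rater_ranks):
        raise ValueError("rank lists must have equal length")
    order = {label: i for i, label in enumerate(scale.labels)}
    exact = sum(p == r for p, r in zip(pred_ranks, rater_ranks))
    fine = sum(abs(order[p] - order[r]) <= 1
               for p, r in zip(pred_ranks, rater_ranks))
    n = len(pred_ranks)
    return {"exact": exact / n if n else 0.0, "fine": fine / n if n else 0.0}
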
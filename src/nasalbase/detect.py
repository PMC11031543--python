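"""Nasal-base localization.

A single-stage anchor-grid detector stands in for a full two-stage
region-proposal detector: a small convolutional trunk over the
downscaled image emits one objectness probability and four box offsets
per anchor location, and is trained with the unified two-term detection
loss (mean binary log loss over sampled anchors plus a weighted mean
smooth-L1 box-regression term over positive anchors).  The model
contract — image in, scored box out — is the same as for a heavier
detector, so one can be swapped in.

Box offsets use the standard parameterization: center offsets
normalized by the anchor size and log size ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import _nn
from .boxes import BoundingBox, iou
from .sample import AnnotatedImage

__all__ = [
    "DetectionLossConfig",
    "AnchorGrid",
    "classification_loss",
    "smooth_l1",
    "detection_loss",
    "Detector",
    "train_detector",
    "evaluate_detection",
]

_EPS = 1e-7


@dataclass(frozen=True)
class DetectionLossConfig:
    """Weights and anchor-labeling thresholds of the detection loss."""

    lambda_balance: float = 1.0
    pos_iou: float = 0.7
    neg_iou: float = 0.3

    def __post_init__(self) -> None:
        if self.lambda_balance < 0:
            raise ValueError("lambda must be >= 0")
        if not (0 <= self.neg_iou <= self.pos_iou <= 1):
            raise ValueError("need 0 <= neg_iou <= pos_iou <= 1")


@dataclass
class AnchorGrid:
    """Regular anchor lattice with per-anchor labels and regression targets.

    ``labels`` is +1 (positive), 0 (negative) or -1 (ignore); ``targets``
    holds the 4-vector t* for positive anchors.  Label assignment is the
    usual convention: positive above the IoU threshold (and always the
    max-IoU anchor, so every box owns at least one anchor), negative
    below the lower threshold, ignored in between.
    """

    centers: np.ndarray          # (A, 2) anchor centers, pixels
    size: float                  # square anchor side, pixels
    labels: np.ndarray | None = None   # (A,)
    targets: np.ndarray | None = None  # (A, 4)

    @classmethod
    def build(cls, image_size: tuple[int, int], grid: tuple[int, int],
              anchor_size: float) -> "AnchorGrid":
        W, H = image_size
        gw, gh = grid
        xs = (np.arange(gw) + 0.5) * (W / gw)
        ys = (np.arange(gh) + 0.5) * (H / gh)
        cx, cy = np.meshgrid(xs, ys)
        centers = np.stack([cx.ravel(), cy.ravel()], axis=1)
        return cls(centers=centers, size=float(anchor_size))

    @property
    def n_locations(self) -> int:
        return len(self.centers)

    def anchor_box(self, i: int) -> BoundingBox:
        cx, cy = self.centers[i]
        h = self.size / 2
        return BoundingBox(cx - h, cy - h, cx + h, cy + h)

    def assign(self, gt: BoundingBox, config: DetectionLossConfig) -> "AnchorGrid":
        ious = np.array([iou(self.anchor_box(i), gt) for i in range(self.n_locations)])
        labels = np.full(self.n_locations, -1, dtype=int)
        labels[ious <= config.neg_iou] = 0
        labels[ious >= config.pos_iou] = 1
        labels[int(np.argmax(ious))] = 1
        gx, gy = gt.center
        targets = np.zeros((self.n_locations, 4))
        targets[:, 0] = (gx - self.centers[:, 0]) / self.size
        targets[:, 1] = (gy - self.centers[:, 1]) / self.size
        targets[:, 2] = np.log(gt.width / self.size)
        targets[:, 3] = np.log(gt.height / self.size)
        return AnchorGrid(self.centers, self.size, labels, targets)

    def decode(self, i: int, t: np.ndarray, score: float | None = None) -> BoundingBox:
        cx = self.centers[i, 0] + t[0] * self.size
        cy = self.centers[i, 1] + t[1] * self.size
        w = self.size * np.exp(t[2])
        h = self.size * np.exp(t[3])
        return BoundingBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2, score=score)


def classification_loss(p: float | np.ndarray, p_star: float | np.ndarray) -> np.ndarray:
    """Binary log loss -log[p* p + (1 - p*)(1 - p)], epsilon-clamped."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1 - _EPS)
    p_star = np.asarray(p_star, dtype=float)
    return -np.log(p_star * p + (1 - p_star) * (1 - p))


def smooth_l1(x: float | np.ndarray) -> np.ndarray:
    """0.5 x^2 inside the unit interval, |x| - 0.5 outside (C1 at |x|=1)."""
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    return np.where(ax < 1, 0.5 * x * x, ax - 0.5)


def detection_loss(p: np.ndarray, t: np.ndarray, anchors: AnchorGrid,
                   config: DetectionLossConfig,
                   n_cls: int | None = None, n_reg: int | None = None) -> float:
    """Unified detection loss over one assigned anchor grid.

    (1/N_cls) sum of log losses over sampled (non-ignored) anchors plus
    lambda (1/N_reg) sum over positive anchors of the summed smooth-L1
    offset errors.  N_cls defaults to the number of sampled anchors and
    N_reg to the number of anchor locations.
    """
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    if anchors.labels is None:
        raise ValueError("anchor grid has no label assignment")
    if p.shape[0] != anchors.n_locations or t.shape != (anchors.n_locations, 4):
        raise ValueError("predictions are not aligned with the anchor grid")
    sampled = anchors.labels >= 0
    pos = anchors.labels == 1
    n_cls = int(n_cls or sampled.sum())
    n_reg = int(n_reg or anchors.n_locations)
    cls_term = classification_loss(p[sampled], anchors.labels[sampled]).sum() / n_cls
    reg_term = smooth_l1(t[pos] - anchors.targets[pos]).sum() / n_reg
    return float(cls_term + config.lambda_balance * reg_term)


# ---------------------------------------------------------------------------
# the trainable detector


def _to_input(image: np.ndarray, input_size: int) -> np.ndarray:
    """Grayscale, resize to the square model input, scale to [-0.5, 0.5]."""
    gray = image.astype(np.float32).mean(axis=2) / np.float32(255.0) - np.float32(0.5)
    if gray.shape != (input_size, input_size):
        gray = resize(gray, (input_size, input_size), anti_aliasing=True).astype(np.float32)
    return gray[None, :, :]


class Detector:
    """Anchor-grid nasal-base detector (single class, one box per image)."""

    def __init__(self, input_size: int = 128,
                 anchor_size: float = 32.0, channels: tuple[int, ...] = (16, 32, 64),
                 refine_channels: int = 64, leaky_slope: float = 0.1, seed: int = 0):
        self.input_size = input_size
        # each strided conv block halves the resolution, fixing the lattice
        self.grid = input_size // (2 ** len(channels))
        self.anchor_size = anchor_size
        self.channels = tuple(channels)
        self.refine_channels = refine_channels
        self.leaky_slope = leaky_slope
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list[_nn.Layer] = []
        cin = 1
        for c in channels:
            layers += [_nn.Conv2d(cin, c, 3, stride=2, rng=rng), _nn.LeakyReLU(leaky_slope)]
            cin = c
        if refine_channels:
            layers += [_nn.Conv2d(cin, refine_channels, 3, stride=1, rng=rng),
                       _nn.LeakyReLU(leaky_slope)]
            cin = refine_channels
        self.trunk = _nn.Sequential(*layers)
        self.obj_head = _nn.Conv2d(cin, 1, 1, stride=1, rng=rng)
        self.box_head = _nn.Conv2d(cin, 4, 1, stride=1, rng=rng)
        self.anchors = AnchorGrid.build((input_size, input_size), (self.grid, self.grid), anchor_size)

    def params(self):
        return self.trunk.params() + self.obj_head.params() + self.box_head.params()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns objectness probabilities (N, A) and offsets (N, A, 4)."""
        feat = self.trunk.forward(x)
        logits = self.obj_head.forward(feat)
        offs = self.box_head.forward(feat)
        n = x.shape[0]
        self._p = _nn.sigmoid(logits.reshape(n, -1))
        return self._p, offs.reshape(n, 4, -1).transpose(0, 2, 1)

    def backward(self, gp: np.ndarray, gt_offs: np.ndarray) -> None:
        """Backprop given dLoss/d(probabilities) and dLoss/d(offsets)."""
        n = gp.shape[0]
        g_logits = gp * self._p * (1 - self._p)
        g = self.obj_head.backward(g_logits.reshape(n, 1, self.grid, self.grid))
        g += self.box_head.backward(
            gt_offs.transpose(0, 2, 1).reshape(n, 4, self.grid, self.grid))
        self.trunk.backward(g)

    def predict(self, image: np.ndarray) -> BoundingBox:
        """Highest-scoring decoded box, in the coordinates of ``image``."""
        h, w = image.shape[:2]
        x = _to_input(image, self.input_size)[None]
        p, offs = self.forward(x)
        i = int(np.argmax(p[0]))
        box = self.anchors.decode(i, offs[0, i], score=float(p[0, i]))
        fx, fy = w / self.input_size, h / self.input_size
        return BoundingBox(box.x_min * fx, box.y_min * fy,
                           box.x_max * fx, box.y_max * fy, score=box.score)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p["value"] for i, p in enumerate(self.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"input_size": self.input_size,
                "anchor_size": self.anchor_size, "channels": list(self.channels),
                "refine_channels": self.refine_channels,
                "leaky_slope": self.leaky_slope, "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Detector":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        det = cls(**{k: meta[k] for k in
                     ("input_size", "anchor_size", "channels", "refine_channels",
                      "leaky_slope", "seed")})
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(det.params()):
            p["value"][...] = data[f"p{i}"]
        return det

    def state_arrays(self) -> list[np.ndarray]:
        return [p["value"].copy() for p in self.params()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.params(), arrays):
            p["value"][...] = a


def _loss_and_grads(det: Detector, p: np.ndarray, offs: np.ndarray,
                    assigned: list[AnchorGrid], config: DetectionLossConfig
                    ) -> tuple[float, np.ndarray, np.ndarray]:
    """Batch detection loss plus gradients w.r.t. probabilities and offsets.

    N_cls counts all sampled anchors in the mini-batch; N_reg counts all
    anchor locations in the mini-batch.
    """
    n, A = p.shape
    labels = np.stack([a.labels for a in assigned])
    targets = np.stack([a.targets for a in assigned])
    sampled = labels >= 0
    pos = labels == 1
    n_cls = int(sampled.sum())
    n_reg = n * A
    pc = np.clip(p, _EPS, 1 - _EPS)
    q = labels * pc + (1 - labels) * (1 - pc)  # labels==-1 rows unused
    loss_cls = -np.log(q[sampled]).sum() / n_cls
    diff = offs - targets
    loss_reg = smooth_l1(diff[pos]).sum() / n_reg
    loss = loss_cls + config.lambda_balance * loss_reg

    gp = np.zeros_like(p)
    gp[sampled] = -(2 * labels[sampled] - 1) / q[sampled] / n_cls
    g_offs = np.zeros_like(offs)
    g_offs[pos] = config.lambda_balance * np.clip(diff[pos], -1, 1) / n_reg
    return float(loss), gp.astype(np.float32), g_offs.astype(np.float32)


def train_detector(
    samples: list[AnnotatedImage],
    val_samples: list[AnnotatedImage] | None = None,
    epochs: int = 30,
    batch_size: int = 8,
    lr: float = 1e-3,
    schedule: str = "step",
    config: DetectionLossConfig | None = None,
    model: Detector | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> tuple[Detector, dict]:
    """Train the anchor-grid detector on annotated face-context images.

    Checkpoints the parameters with the best validation loss (an 80/20
    tail split of ``samples`` when no validation set is given).  The run
    is a pure function of the data and ``seed``.
    """
    if not samples:
        raise ValueError("empty training set")
    config = config or DetectionLossConfig()
    det = model or Detector(seed=seed)
    if val_samples is None:
        n_val = max(1, len(samples) // 5)
        val_samples, samples = samples[-n_val:], samples[:-n_val]

    def prep(ss: list[AnnotatedImage]):
        xs, assigned = [], []
        for s in ss:
            if s.box is None:
                raise ValueError("training sample lacks a ground-truth box")
            h, w = s.image.shape[:2]
            fx = det.input_size / w
            fy = det.input_size / h
            gt = BoundingBox(s.box.x_min * fx, s.box.y_min * fy,
                             s.box.x_max * fx, s.box.y_max * fy)
            xs.append(_to_input(s.image, det.input_size))
            assigned.append(det.anchors.assign(gt, config))
        return np.stack(xs), assigned

    X, assigned = prep(samples)
    Xv, assigned_v = prep(val_samples)
    opt = _nn.Adam(det.params(), lr=lr)
    sched = _nn.lr_schedule(schedule, lr, epochs, step_every=max(10, epochs // 3))
    rng = np.random.default_rng(seed)
    best = (np.inf, det.state_arrays())
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(epochs):
        opt.lr = sched(epoch)
        order = rng.permutation(len(samples))
        ep_loss = 0.0
        for k in range(0, len(order), batch_size):
            idx = order[k:k + batch_size]
            p, offs = det.forward(X[idx])
            loss, gp, goffs = _loss_and_grads(det, p, offs,
                                              [assigned[i] for i in idx], config)
            det.backward(gp, goffs)
            opt.step()
            ep_loss += loss * len(idx)
        pv, offsv = det.forward(Xv)
        val_loss, _, _ = _loss_and_grads(det, pv, offsv, assigned_v, config)
        history["train_loss"].append(ep_loss / len(samples))
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, det.state_arrays())
        if verbose:
            print(f"epoch {epoch:3d} train {history['train_loss'][-1]:.4f} val {val_loss:.4f}")
    det.set_state(best[1])
    history["best_val_loss"] = best[0]
    return det, history


# ---------------------------------------------------------------------------
# detection metrics


def evaluate_detection(
    predictions: list[tuple[int, BoundingBox]],
    ground_truths: list[tuple[int, BoundingBox]],
    iou_threshold: float = 0.5,
) -> dict:
    """Precision/recall/F1 and 11-point interpolated AP for one class.

    ``predictions`` are (image_index, scored box); matching is greedy in
    score order, each prediction taking the best-IoU unmatched ground
    truth of its image.  AP is the mean of the interpolated precision
    (max precision at recall >= r) at r = 0.0, 0.1, ..., 1.0; with a
    single class, mAP equals AP.
    """
    preds = sorted(predictions, key=lambda ib: -(ib[1].score or 0.0))
    gt_by_img: dict[int, list[BoundingBox]] = {}
    for img, box in ground_truths:
        gt_by_img.setdefault(img, []).append(box)
    matched: dict[int, set[int]] = {img: set() for img in gt_by_img}
    n_gt = len(ground_truths)
    tp = np.zeros(len(preds))
    for r, (img, box) in enumerate(preds):
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gt_by_img.get(img, [])):
            if j in matched[img]:
                continue
            v = iou(box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[r] = 1
            matched[img].add(best_j)
    cum_tp = np.cumsum(tp)
    ranks = np.arange(1, len(preds) + 1)
    prec_curve = cum_tp / ranks if len(preds) else np.array([])
    rec_curve = cum_tp / n_gt if n_gt else np.zeros(len(preds))
    precision = float(prec_curve[-1]) if len(preds) else 0.0
    recall = float(rec_curve[-1]) if len(preds) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    ap = 0.0
    for r in np.linspace(0, 1, 11):
        mask = rec_curve >= r - 1e-12
        ap += float(prec_curve[mask].max()) if mask.any() else 0.0
    ap /= 11
    return {"precision": precision, "recall": recall, "F1": f1,
            "AP11": ap, "mAP": ap}
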
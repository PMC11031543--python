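"""Detection: box construction, the unified loss against a scalar-loop
oracle, and PR/AP metrics against a brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

from nasalbase.boxes import BoundingBox, ground_truth_box, iou
from nasalbase.detect import (AnchorGrid, DetectionLossConfig, classification_loss,
                              detection_loss, evaluate_detection, smooth_l1)
from nasalbase.schema import LandmarkSet


def _lms_with_extent(x0, x1, y0, y1):
    rng = np.random.default_rng(0)
    pts = rng.uniform([x0, y0], [x1, y1], (18, 2))
    pts[0] = [x0, y0]
    pts[1] = [x1, y1]
    return LandmarkSet(image_id="t", points=pts, frame_size=(0, 0))


class TestGroundTruthBox:
    def test_tight_box_no_pad(self):
        box = ground_truth_box(_lms_with_extent(40, 80, 100, 140), pad=0.0)
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == (40, 100, 80, 140)

    def test_half_pad_expands_half_size_per_side(self):
        box = ground_truth_box(_lms_with_extent(40, 80, 100, 140), pad=0.5)
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == (20, 80, 100, 160)

    def test_render_box_contains_all_landmarks(self, symmetric_sample):
        box = ground_truth_box(symmetric_sample.landmarks)
        pts = symmetric_sample.landmarks.points
        assert (pts[:, 0] >= box.x_min).all() and (pts[:, 0] <= box.x_max).all()
        assert (pts[:, 1] >= box.y_min).all() and (pts[:, 1] <= box.y_max).all()


class TestIoU:
    @pytest.mark.parametrize("b,expected", [
        (BoundingBox(0, 0, 10, 10), 1.0),
        (BoundingBox(20, 20, 30, 30), 0.0),
        (BoundingBox(5, 0, 15, 10), 1 / 3),
    ])
    def test_hand_cases(self, b, expected):
        assert iou(BoundingBox(0, 0, 10, 10), b) == pytest.approx(expected, abs=1e-12)


class TestLossPieces:
    def test_classification_loss_values(self):
        assert classification_loss(1.0, 1) == pytest.approx(0.0, abs=1e-6)
        assert classification_loss(0.5, 1) == pytest.approx(-np.log(0.5), abs=1e-9)
        assert classification_loss(0.5, 0) == pytest.approx(-np.log(0.5), abs=1e-9)
        assert classification_loss(0.9, 0) == pytest.approx(-np.log(0.1), abs=1e-7)

    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5),
                                            (-0.5, 0.125), (-2.0, 1.5)])
    def test_smooth_l1_values(self, x, expected):
        assert smooth_l1(x) == pytest.approx(expected, abs=1e-12)

    def test_smooth_l1_continuous_and_c1_at_one(self):
        eps = 1e-8
        assert smooth_l1(1 - eps) == pytest.approx(smooth_l1(1 + eps), abs=1e-7)
        d_in = (smooth_l1(1.0) - smooth_l1(1 - 1e-6)) / 1e-6
        d_out = (smooth_l1(1 + 1e-6) - smooth_l1(1.0)) / 1e-6
        assert d_in == pytest.approx(1.0, abs=1e-4)
        assert d_out == pytest.approx(1.0, abs=1e-4)


def _three_anchor_grid():
    anchors = AnchorGrid(centers=np.array([[10., 10.], [30., 10.], [50., 10.]]),
                         size=20.0,
                         labels=np.array([1, 0, -1]),
                         targets=np.array([[0.1, -0.2, 0.05, 0.0],
                                           [0, 0, 0, 0], [0, 0, 0, 0.]]))
    return anchors


class TestDetectionLoss:
    def test_no_positive_anchors_pure_classification(self):
        anchors = _three_anchor_grid()
        anchors.labels = np.array([0, 0, -1])
        p = np.array([0.2, 0.3, 0.9])
        t = np.zeros((3, 4))
        expected = (-np.log(0.8) - np.log(0.7)) / 2
        got = detection_loss(p, t, anchors, DetectionLossConfig())
        assert got == pytest.approx(expected, abs=1e-9)

    def test_perfect_predictions_give_zero(self):
        anchors = _three_anchor_grid()
        p = np.array([1.0, 0.0, 0.5])
        t = anchors.targets.copy()
        got = detection_loss(p, t, anchors, DetectionLossConfig())
        assert got == pytest.approx(0.0, abs=1e-5)

    def test_matches_scalar_loop_oracle(self):
        anchors = _three_anchor_grid()
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, 3)
        t = rng.normal(0, 1, (3, 4))
        lam = 1.7
        got = detection_loss(p, t, anchors, DetectionLossConfig(lambda_balance=lam))

        # independent scalar loop
        n_cls = 2   # sampled anchors (labels 0/1)
        n_reg = 3   # anchor locations
        cls_sum = 0.0
        for i in range(3):
            ps = anchors.labels[i]
            if ps < 0:
                continue
            cls_sum += -np.log(ps * p[i] + (1 - ps) * (1 - p[i]))
        reg_sum = 0.0
        for i in range(3):
            if anchors.labels[i] == 1:
                for j in range(4):
                    x = t[i, j] - anchors.targets[i, j]
                    reg_sum += 0.5 * x * x if abs(x) < 1 else abs(x) - 0.5
        expected = cls_sum / n_cls + lam * reg_sum / n_reg
        assert got == pytest.approx(expected, abs=1e-9)

    def test_nonnegative(self):
        anchors = _three_anchor_grid()
        rng = np.random.default_rng(8)
        for _ in range(20):
            got = detection_loss(rng.uniform(0.01, 0.99, 3), rng.normal(0, 2, (3, 4)),
                                 anchors, DetectionLossConfig())
            assert got >= 0

    def test_misaligned_shapes_rejected(self):
        anchors = _three_anchor_grid()
        with pytest.raises(ValueError):
            detection_loss(np.zeros(2), np.zeros((3, 4)), anchors, DetectionLossConfig())


class TestAnchorAssignment:
    def test_max_iou_anchor_always_positive(self):
        grid = AnchorGrid.build((128, 128), (8, 8), 32.0)
        gt = BoundingBox(2, 2, 20, 18)  # poor IoU with every anchor
        assigned = grid.assign(gt, DetectionLossConfig())
        assert (assigned.labels == 1).sum() >= 1

    def test_decode_inverts_targets(self):
        grid = AnchorGrid.build((128, 128), (8, 8), 32.0)
        gt = BoundingBox(30, 40, 80, 95)
        assigned = grid.assign(gt, DetectionLossConfig())
        i = int(np.argmax(assigned.labels))
        box = grid.decode(i, assigned.targets[i])
        assert np.allclose(box.as_array(), gt.as_array(), atol=1e-9)


def _brute_force_ap11(preds, gts, thr):
    scores = sorted({b.score for _, b in preds}, reverse=True)
    pr = []
    for cut in scores:
        sub = [(i, b) for i, b in preds if b.score >= cut]
        res = evaluate_detection(sub, gts, thr)
        pr.append((res["recall"], res["precision"]))
    ap = 0.0
    for r in np.linspace(0, 1, 11):
        cands = [p for rec, p in pr if rec >= r - 1e-12]
        ap += max(cands) if cands else 0.0
    return ap / 11


class TestEvaluateDetection:
    def test_perfect_predictions(self):
        gts = [(i, BoundingBox(10 * i, 0, 10 * i + 8, 8)) for i in range(4)]
        preds = [(i, BoundingBox(10 * i, 0, 10 * i + 8, 8, score=1.0)) for i in range(4)]
        res = evaluate_detection(preds, gts, 0.5)
        assert res["precision"] == res["recall"] == res["F1"] == 1.0
        assert res["AP11"] == pytest.approx(1.0) and res["mAP"] == res["AP11"]

    def test_no_predictions(self):
        gts = [(0, BoundingBox(0, 0, 5, 5))]
        res = evaluate_detection([], gts, 0.5)
        assert res["recall"] == 0.0 and res["AP11"] == 0.0

    def test_ap11_matches_brute_force_on_toy_set(self):
        rng = np.random.default_rng(17)
        gts, preds = [], []
        for i in range(6):
            x = 20.0 * i
            gts.append((i, BoundingBox(x, 0, x + 10, 10)))
        for k in range(10):
            i = k % 6
            x = 20.0 * i + rng.uniform(-6, 6)
            preds.append((i, BoundingBox(x, rng.uniform(-3, 3), x + 10, 10,
                                         score=float(rng.uniform(0, 1)))))
        res = evaluate_detection(preds, gts, 0.5)
        assert res["AP11"] == pytest.approx(_brute_force_ap11(preds, gts, 0.5), abs=1e-9)

    def test_agrees_with_naive_matcher_on_random_sets(self):
        rng = np.random.default_rng(99)
        for trial in range(5):
            gts, preds = [], []
            for i in range(4):
                x = 15.0 * i
                gts.append((i, BoundingBox(x, 0, x + 10, 10)))
                for _ in range(rng.integers(0, 3)):
                    preds.append((i, BoundingBox(x + rng.uniform(-8, 8), 0, x + 10, 10,
                                                 score=float(rng.uniform(0, 1)))))
            res = evaluate_detection(preds, gts, 0.5)
            # naive matcher: same greedy rule written as an O(n^2) loop
            order = sorted(range(len(preds)), key=lambda k: -preds[k][1].score)
            used = set()
            tp = 0
            for k in order:
                img, box = preds[k]
                best, bj = 0.0, None
                for j, (gi, gb) in enumerate(gts):
                    if gi == img and j not in used:
                        v = iou(box, gb)
                        if v > best:
                            best, bj = v, j
                if bj is not None and best >= 0.5:
                    tp += 1
                    used.add(bj)
            if preds:
                assert res["precision"] == pytest.approx(tp / len(preds))
            assert res["recall"] == pytest.approx(tp / len(gts))
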
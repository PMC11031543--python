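"""Shared fixtures.

The trained-model fixtures are deliberately session-scoped: the
scaled-down learning experiments (detector, crop and whole-image
landmark regressors, fusion model) are each trained once per session
and shared between the unit tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from nasalbase.boxes import ground_truth_box
from nasalbase.detect import DetectionLossConfig, Detector, train_detector
from nasalbase.landmarks import RegressorConfig, crop_and_reproject, train_regressor
from nasalbase.symmetry import CombinedConfig, prepare_symmetry_sample, train_combined
from nasalbase.synth import AsymmetryVector, NoseParams, generate_samples, render_nasal_base


@pytest.fixture(scope="session")
def symmetric_sample():
    return render_nasal_base(NoseParams(seed=5))


@pytest.fixture(scope="session")
def asymmetric_sample():
    v = np.array([0.15, -0.2, 0.1, 0.05, -0.1, 0.2, -0.25, 0.15, 0.1])
    params = NoseParams(seed=6).with_asymmetry(AsymmetryVector(v))
    return render_nasal_base(params), v


@pytest.fixture(scope="session")
def trained_detector():
    """Detector trained on synthetic face-context images (fixed seed),
    plus a held-out evaluation set."""
    data = [s for s, _ in generate_samples(170, 0.3, seed=11, embed=True)]
    train, test = data[:140], data[140:]
    det, history = train_detector(
        train, epochs=45, lr=1e-3, seed=0,
        config=DetectionLossConfig(pos_iou=0.5, neg_iou=0.3))
    return det, history, train, test


@pytest.fixture(scope="session")
def trained_regressor():
    """Crop-trained landmark regressor (fixed seed) with held-out crops."""
    data = [s for s, _ in generate_samples(2460, 0.3, seed=21)]
    crops = [crop_and_reproject(s, s.box, out_size=64) for s in data]
    train, test = crops[:2400], crops[2400:]
    reg, history = train_regressor(train, RegressorConfig(epochs=35, seed=0))
    return reg, history, test


@pytest.fixture(scope="session")
def model_comparison_data():
    """Shared small-budget dataset for the crop vs whole-image comparison:
    face-context images, where localization actually matters."""
    return [s for s, _ in generate_samples(260, 0.3, seed=31, embed=True)]


@pytest.fixture(scope="session")
def model_comparison(model_comparison_data):
    """Model II (crop-trained) and Model I (whole-image-trained) landmark
    regressors under a shared seed and budget, with the shared test set."""
    from nasalbase.boxes import BoundingBox

    data = model_comparison_data
    train, test = data[:200], data[200:]
    cfg = RegressorConfig(epochs=30, seed=0)
    crops = [crop_and_reproject(s, s.box, out_size=64) for s in train]
    model_ii, _ = train_regressor(crops, cfg)
    h, w = train[0].image.shape[:2]
    whole = [crop_and_reproject(s, BoundingBox(0, 0, w, h), out_size=64)
             for s in train]
    model_i, _ = train_regressor(whole, cfg)
    return model_i, model_ii, train, test


@pytest.fixture(scope="session")
def trained_combined():
    """Fusion model trained against SSIM targets (fixed seed) + test set."""
    pairs = generate_samples(600, 0.3, seed=7)
    samples = [prepare_symmetry_sample(s) for s, _ in pairs]
    train, test = samples[:480], samples[480:]
    model, history = train_combined(train, CombinedConfig(epochs=300, seed=0))
    return model, history, test


@pytest.fixture(scope="session")
def trained_pipeline(trained_detector, trained_combined):
    """Full assessment pipeline assembled from the session models, with a
    regressor trained on jittered boxes so it tolerates detector noise."""
    from nasalbase.landmarks import jitter_box
    from nasalbase.pipeline import PipelineConfig, TrainedPipeline

    det = trained_detector[0]
    combined = trained_combined[0]
    data = [s for s, _ in generate_samples(1260, 0.3, seed=21)]
    rng = np.random.default_rng(99)
    crops = []
    for s in data[:1200]:
        h, w = s.image.shape[:2]
        crops.append(crop_and_reproject(s, jitter_box(s.box, rng, frame_size=(w, h)),
                                        out_size=64))
    reg, _ = train_regressor(crops, RegressorConfig(epochs=25, seed=0))
    return TrainedPipeline(det, reg, combined, PipelineConfig(seed=0))
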
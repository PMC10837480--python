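"""Shared fixtures: analytic director grids and one trained classifier.

The classifier is trained once per session on the frozen synthetic benchmark
conditions (150 base ROIs per class over three noise levels, eightfold
augmentation) and reused by every test that needs a trained model.
"""

from __future__ import annotations

import numpy as np
import pytest

from nemadetect.cnn import TrainConfig, augment, train
from nemadetect.fields import DirectorGrid
from nemadetect.synthetic import Defect, generate_labeled_rois, ideal_defect_angle

TRAIN_SEED = 11
TEST_SEED = 202
MODERATE_KAPPA = 3.0


def make_ideal_grid(
    defects: list[Defect],
    n: int = 41,
    spacing: float = 0.25,
    center: tuple[float, float] = (0.0, 0.0),
    nudge: float = 1e-9,
) -> DirectorGrid:
    """DirectorGrid sampling the analytic plane field around ``center``."""
    ax = (np.arange(n) - n // 2) * spacing
    X, Y = np.meshgrid(center[0] + ax, center[1] + ax)
    theta = ideal_defect_angle(X + nudge, Y + nudge, defects)
    return DirectorGrid(
        theta=theta,
        origin=(center[0] + ax[0], center[1] + ax[0]),
        spacing=spacing,
    )


def ideal_patch(
    charge: float, phase: float = 0.0, side: int = 9, spacing: float = 0.75,
    core: tuple[float, float] = (0.1, -0.07),
) -> np.ndarray:
    """Analytic single-defect 9x9 patch with the core jittered off-node."""
    half = spacing * (side - 1) / 2.0
    ax = np.linspace(-half, half, side)
    X, Y = np.meshgrid(ax, ax)
    return ideal_defect_angle(X, Y, [Defect(core[0], core[1], charge, phase)])


@pytest.fixture(scope="session")
def train_dataset():
    return generate_labeled_rois(
        150, (None, 8.0, MODERATE_KAPPA), seed=TRAIN_SEED
    )


@pytest.fixture(scope="session")
def test_dataset():
    return generate_labeled_rois(200, (None, MODERATE_KAPPA), seed=TEST_SEED)


@pytest.fixture(scope="session")
def trained_model(train_dataset):
    model, log = train(augment(train_dataset), TrainConfig(seed=7))
    model.training_log = log  # stashed for tests that inspect the curve
    return model
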
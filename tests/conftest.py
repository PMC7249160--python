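"""Shared fixtures: tiny synthetic scenes and quickly trained toy models."""

from __future__ import annotations

import numpy as np
import pytest

from earcount.classifier import ClassifierConfig, train_classifier
from earcount.patches import KERNEL, NON_KERNEL, Patch, PatchDataset
from earcount.regressor import RegressorConfig, train_regressor
from earcount.synthetic import EarSceneParams, render_ear_image

YELLOW = (215, 190, 40)
GREEN = (40, 150, 60)


def _green_noise(rng, shape=(32, 32)):
    return np.clip(
        np.full((*shape, 3), GREEN, dtype=float) + rng.normal(0, 6, (*shape, 3)),
        0, 255,
    )


def paint_blob(pixels, cx, cy, a=6.0, b=9.0):
    """Draw a shaded yellow ellipse (a synthetic kernel) into a float image."""
    h, w = pixels.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = ((xx + 0.5 - cx) / a) ** 2 + ((yy + 0.5 - cy) / b) ** 2
    mask = d2 <= 1
    shade = 1.0 - 0.35 * d2[mask]
    pixels[mask] = np.array(YELLOW, dtype=float) * shade[:, None]
    return pixels


def _toy_patch(rng, label):
    pixels = _green_noise(rng)
    center = None
    if label == KERNEL:
        cx, cy = rng.uniform(11, 21, size=2)
        paint_blob(pixels, cx, cy)
        center = (float(cx), float(cy))
    return Patch(pixels=pixels.astype(np.uint8), label=label, center=center)


@pytest.fixture(scope="session")
def toy_patches():
    """Separable toy fixture: a yellow kernel blob on green noise vs plain
    green noise, with the blob center as the regression target."""
    rng = np.random.default_rng(42)
    patches = [_toy_patch(rng, KERNEL) for _ in range(120)]
    patches += [_toy_patch(rng, NON_KERNEL) for _ in range(120)]
    order = rng.permutation(len(patches))
    return PatchDataset([patches[i] for i in order], rng_seed=42)


@pytest.fixture(scope="session")
def toy_split(toy_patches):
    from earcount.patches import split_dataset

    return split_dataset(toy_patches, 0.25, rng_seed=7)


@pytest.fixture(scope="session")
def toy_classifier(toy_split):
    """CNN trained to perfection on the separable toy fixture."""
    train, test = toy_split
    config = ClassifierConfig(batch_size=32, total_iterations=150, eval_interval=50,
                              lr_initial=2e-3, lr_reduced=1e-3, rng_seed=3)
    model, history = train_classifier(train, test, config)
    return model, history, test


@pytest.fixture(scope="session")
def toy_regressor(toy_split):
    """Regressor trained on the toy positives (all centered at (16, 16))."""
    train, test = toy_split
    config = RegressorConfig(batch_size=16, total_iterations=400, eval_interval=100,
                             lr=1e-3, rng_seed=5)
    model, history = train_regressor(train.positives(), test.positives(), config)
    return model, history, test.positives()


@pytest.fixture(scope="session")
def small_scene():
    """A small single-ear scene used across detection/counting tests."""
    params = EarSceneParams(
        image_size=(288, 160), visible_columns=(9, 11), kernels_per_column=(10, 12),
        kernel_radius=(5.0, 6.0), ear_tilt=(-6.0, 6.0), jitter=0.3, rng_seed=77,
    )
    return render_ear_image(params)
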
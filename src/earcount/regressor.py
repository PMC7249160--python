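"""CNN regression of the kernel center inside a 32x32 patch.

Dense ears make bounding-box overlays unreadable and kernels are often
off-center in their detection window, so the pipeline marks each detected
kernel with a regressed (x, y) center point instead.  Architecture (3x3
unpadded convolutions, ReLU after every layer except the final FC):

    conv32 -> conv32 -> maxpool2/s2 -> conv64 -> conv64 -> conv64
    -> maxpool2/s2 -> FC-100 -> FC-50 -> FC-10 -> FC-2

No batch normalisation and no dropout.  The head predicts the center in
normalised patch units [0, 1]^2 (scaled to pixels at the interface) and is
trained with the smooth-L1 loss evaluated in pixel units, which is less
sensitive to outliers than squared error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .classifier import TrainingHistory, _patch_array
from .patches import PATCH_SIZE, Patch, PatchDataset

__all__ = [
    "RegressorConfig",
    "CenterPrediction",
    "build_cnn_regressor",
    "smooth_l1_loss",
    "train_regressor",
    "predict_center",
    "center_to_image_coords",
]

INPUT_SHAPE = (PATCH_SIZE, PATCH_SIZE, 3)


@dataclass(frozen=True)
class RegressorConfig:
    batch_size: int = 45
    total_iterations: int = 25_000
    lr: float = 3e-4  # "0.03%"
    eval_interval: int = 100
    rng_seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass(frozen=True)
class CenterPrediction:
    patch_xy: tuple[float, float]  # in [0, 32)
    image_xy: tuple[float, float] | None = None


def build_cnn_regressor(rng_seed: int = 0) -> nn.Network:
    rng = np.random.default_rng(rng_seed)

    def conv_relu(cin, cout):
        return [nn.Conv2D(cin, cout, 3, rng), nn.ReLU()]

    layers = (
        conv_relu(3, 32) + conv_relu(32, 32)
        + [nn.MaxPool(2)]
        + conv_relu(32, 64) + conv_relu(64, 64) + conv_relu(64, 64)
        + [nn.MaxPool(2), nn.Flatten()]
        + [nn.Dense(4 * 4 * 64, 100, rng), nn.ReLU(),
           nn.Dense(100, 50, rng), nn.ReLU(),
           nn.Dense(50, 10, rng), nn.ReLU(),
           nn.Dense(10, 2, rng)]  # linear output, normalised patch units
    )
    return nn.Network(layers, INPUT_SHAPE, meta={"kind": "center_regressor",
                                                 "rng_seed": rng_seed})


def smooth_l1_loss(predicted, target) -> float:
    """Smooth-L1 between two (x, y) pairs, summed over the coordinates.

    Per coordinate: 0.5 d^2 for |d| < 1, |d| - 0.5 otherwise; the two
    branches agree (0.5) at |d| = 1.  Units are pixels.
    """
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if predicted.shape != target.shape:
        raise ValueError("predicted and target must have the same shape")
    return float(nn.smooth_l1(predicted - target).sum(axis=-1))


def _targets(dataset: PatchDataset) -> tuple[np.ndarray, np.ndarray]:
    x, _, centers = dataset.as_arrays(with_centers=True)
    if np.isnan(centers).any():
        raise ValueError("every regression patch must carry a kernel center")
    return x, centers


def _eval_loss(model: nn.Network, x: np.ndarray, t: np.ndarray, batch: int = 512) -> float:
    total = 0.0
    for i in range(0, len(x), batch):
        pred_px = model.forward(x[i : i + batch], train=False) * PATCH_SIZE
        total += nn.smooth_l1(pred_px - t[i : i + batch]).sum()
    return total / len(x)


def train_regressor(train: PatchDataset, test: PatchDataset,
                    config: RegressorConfig = RegressorConfig(),
                    model: nn.Network | None = None) -> tuple[nn.Network, TrainingHistory]:
    """Seed-deterministic Adam training against smooth-L1 in pixel units."""
    x_train, t_train = _targets(train)
    x_test, t_test = _targets(test)
    if model is None:
        model = build_cnn_regressor(config.rng_seed)
    rng = np.random.default_rng(config.rng_seed + 1)
    optimizer = nn.Adam(model.params)
    history = TrainingHistory()

    running, n_since = 0.0, 0
    order = rng.permutation(len(x_train))
    cursor = 0
    for it in range(1, config.total_iterations + 1):
        if cursor + config.batch_size > len(order):
            order = rng.permutation(len(x_train))
            cursor = 0
        idx = order[cursor : cursor + config.batch_size]
        cursor += config.batch_size
        pred_px = model.forward(x_train[idx], train=True) * PATCH_SIZE
        residual = pred_px - t_train[idx]
        loss = nn.smooth_l1(residual).sum(axis=1).mean()
        dpred = nn.smooth_l1_grad(residual).astype(np.float32) / len(idx) * PATCH_SIZE
        model.backward(dpred)
        optimizer.step(model.grads, config.lr)
        running += float(loss)
        n_since += 1
        if it % config.eval_interval == 0 or it == config.total_iterations:
            history.iterations.append(it)
            history.train_loss.append(running / n_since)
            history.test_loss.append(_eval_loss(model, x_test, t_test))
            history.learning_rate.append(config.lr)
            running, n_since = 0.0, 0
    model.meta["trained"] = True
    return model, history


def predict_center(model: nn.Network, patches):
    """Predicted in-patch center(s), clamped to [0, 32).

    Returns a :class:`CenterPrediction` for a single patch, else an (N, 2)
    array.
    """
    single = isinstance(patches, Patch) or (
        isinstance(patches, np.ndarray) and np.asarray(patches).ndim == 3
    )
    x = _patch_array(patches)
    out = np.concatenate([
        model.forward(x[i : i + 512], train=False) for i in range(0, len(x), 512)
    ]) * PATCH_SIZE
    out = np.clip(out, 0.0, np.nextafter(np.float32(PATCH_SIZE), np.float32(0)))
    if single:
        return CenterPrediction(patch_xy=(float(out[0, 0]), float(out[0, 1])))
    return out


def center_to_image_coords(prediction, window) -> tuple[float, float]:
    """Map a patch-coordinate center back through the window's rescale.

    ``window`` is any object with x, y, width, height (the scored sliding
    window the patch was cut from); the patch was rescaled from that window
    to 32x32, so the inverse map is linear per axis.
    """
    if isinstance(prediction, CenterPrediction):
        px, py = prediction.patch_xy
    else:
        px, py = prediction
    return (window.x + px * window.width / PATCH_SIZE,
            window.y + py * window.height / PATCH_SIZE)
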
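"""Kernel/non-kernel patch classifier.

The CNN takes a 32x32x3 patch and emits a confidence that the patch shows a
single corn kernel.  Architecture (all convolutions 3x3, unpadded, stride
1; batch normalisation + ReLU after every conv and hidden FC layer):

    conv32 -> conv32 -> avgpool2/s2 -> conv64 -> conv64 -> conv64
    -> avgpool7/s1 -> FC-256 -> FC-128 -> FC-1 -> sigmoid

Training minimises the log loss with Adam over shuffled mini-batches,
starting from Xavier-initialised weights; the learning rate drops once from
``lr_initial`` to ``lr_reduced`` when the test loss plateaus.  A classical
HOG + linear-SVM baseline with the same predict interface is provided for
comparison, along with the confusion-count metrics used to judge both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .patches import PATCH_SIZE, Patch, PatchDataset

__all__ = [
    "ClassifierConfig",
    "ClassificationMetrics",
    "TrainingHistory",
    "build_cnn_classifier",
    "train_classifier",
    "predict_confidence",
    "HogSvmClassifier",
    "hog_svm_classifier",
    "classification_metrics",
]

INPUT_SHAPE = (PATCH_SIZE, PATCH_SIZE, 3)


@dataclass(frozen=True)
class ClassifierConfig:
    batch_size: int = 128
    total_iterations: int = 25_000
    lr_initial: float = 3e-4  # "0.03%"
    lr_reduced: float = 1e-4  # "0.01%"
    plateau_patience: int = 5  # evaluations without improvement before the drop
    plateau_min_delta: float = 1e-4
    eval_interval: int = 100  # iterations between test-loss evaluations
    rng_seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.lr_reduced <= self.lr_initial:
            raise ValueError("need 0 < lr_reduced <= lr_initial")


@dataclass
class TrainingHistory:
    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class ClassificationMetrics:
    fp: int
    fn: int
    accuracy: float
    f_score: float
    n: int

    def rounded(self, digits: int = 3) -> "ClassificationMetrics":
        return ClassificationMetrics(self.fp, self.fn, round(self.accuracy, digits),
                                     round(self.f_score, digits), self.n)

    def as_dict(self) -> dict:
        return {"fp": self.fp, "fn": self.fn, "accuracy": self.accuracy,
                "f_score": self.f_score, "n": self.n}


def build_cnn_classifier(rng_seed: int = 0) -> nn.Network:
    rng = np.random.default_rng(rng_seed)

    def conv_bn_relu(cin, cout):
        return [nn.Conv2D(cin, cout, 3, rng), nn.BatchNorm(cout), nn.ReLU()]

    def dense_bn_relu(nin, nout):
        return [nn.Dense(nin, nout, rng), nn.BatchNorm(nout), nn.ReLU()]

    layers = (
        conv_bn_relu(3, 32) + conv_bn_relu(32, 32)
        + [nn.AvgPool(2, 2)]
        + conv_bn_relu(32, 64) + conv_bn_relu(64, 64) + conv_bn_relu(64, 64)
        + [nn.AvgPool(7, 1), nn.Flatten()]
        + dense_bn_relu(2 * 2 * 64, 256) + dense_bn_relu(256, 128)
        + [nn.Dense(128, 1, rng)]  # logit; sigmoid applied at the interface
    )
    return nn.Network(layers, INPUT_SHAPE, meta={"kind": "kernel_classifier",
                                                 "rng_seed": rng_seed})


def _patch_array(patches) -> np.ndarray:
    if isinstance(patches, PatchDataset):
        x, _ = patches.as_arrays()
        return x
    if isinstance(patches, Patch):
        return patches.pixels.astype(np.float32)[None] / 255.0
    arr = np.asarray(patches)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    arr = arr.astype(np.float32, copy=False)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[1:] != INPUT_SHAPE:
        raise ValueError(f"expected patches of shape {INPUT_SHAPE}, got {arr.shape}")
    return arr


def _eval_bce(model: nn.Network, x: np.ndarray, y: np.ndarray, batch: int = 512) -> float:
    total = 0.0
    for i in range(0, len(x), batch):
        logits = model.forward(x[i : i + batch], train=False)[:, 0]
        loss, _ = nn.bce_with_logits(logits, y[i : i + batch])
        total += loss * len(logits)
    return total / len(x)


def train_classifier(train: PatchDataset, test: PatchDataset,
                     config: ClassifierConfig = ClassifierConfig(),
                     model: nn.Network | None = None) -> tuple[nn.Network, TrainingHistory]:
    """Seed-deterministic mini-batch training of the patch CNN."""
    x_train, y_train = train.as_arrays()
    x_test, y_test = test.as_arrays()
    if y_train.min() == y_train.max():
        raise ValueError("training set must contain both classes")

    if model is None:
        model = build_cnn_classifier(config.rng_seed)
    rng = np.random.default_rng(config.rng_seed + 1)
    optimizer = nn.Adam(model.params)
    history = TrainingHistory()

    lr = config.lr_initial
    best_test = np.inf
    stall = 0
    running = 0.0
    n_since_eval = 0
    order = rng.permutation(len(x_train))
    cursor = 0
    for it in range(1, config.total_iterations + 1):
        if cursor + config.batch_size > len(order):
            order = rng.permutation(len(x_train))
            cursor = 0
        idx = order[cursor : cursor + config.batch_size]
        cursor += config.batch_size
        logits = model.forward(x_train[idx], train=True)[:, 0]
        loss, dlogits = nn.bce_with_logits(logits, y_train[idx])
        model.backward(dlogits[:, None])
        optimizer.step(model.grads, lr)
        running += loss
        n_since_eval += 1

        if it % config.eval_interval == 0 or it == config.total_iterations:
            test_loss = _eval_bce(model, x_test, y_test)
            history.iterations.append(it)
            history.train_loss.append(running / n_since_eval)
            history.test_loss.append(test_loss)
            history.learning_rate.append(lr)
            running, n_since_eval = 0.0, 0
            if lr > config.lr_reduced:
                if test_loss < best_test - config.plateau_min_delta:
                    best_test = test_loss
                    stall = 0
                else:
                    stall += 1
                    if stall >= config.plateau_patience:
                        lr = config.lr_reduced
    model.meta["trained"] = True
    return model, history


def predict_confidence(model: nn.Network, patches):
    """Kernel confidence in [0, 1]; scalar for a single patch, else a vector.

    Uses accumulated batch-norm running statistics (inference mode), so
    batched and per-patch evaluation agree.
    """
    single = isinstance(patches, Patch) or (
        isinstance(patches, np.ndarray) and patches.ndim == 3
    )
    x = _patch_array(patches)
    out = np.concatenate([
        nn.sigmoid(model.forward(x[i : i + 512], train=False)[:, 0])
        for i in range(0, len(x), 512)
    ])
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# HOG + SVM baseline

HOG_PIXELS_PER_CELL = (4, 4)
HOG_CELLS_PER_BLOCK = (2, 2)
HOG_ORIENTATIONS = 9
# ((32/4 - 2) + 1)^2 blocks x 2x2 cells x 9 bins
HOG_DESCRIPTOR_LENGTH = 7 * 7 * 2 * 2 * 9


class HogSvmClassifier:
    """HOG descriptors (4x4 cells, 2x2-cell blocks, 9 bins) + linear SVM.

    Exposes the same ``predict_confidence`` interface as the CNN; the SVM
    decision value is squashed through a logistic so thresholding at 0.5
    reproduces the sign of the margin.
    """

    def __init__(self, c: float = 1.0):
        from sklearn.svm import LinearSVC

        self.svm = LinearSVC(C=c)
        self.fitted = False

    @staticmethod
    def descriptors(patches) -> np.ndarray:
        from skimage.color import rgb2gray
        from skimage.feature import hog

        x = _patch_array(patches)
        feats = np.empty((len(x), HOG_DESCRIPTOR_LENGTH), dtype=np.float64)
        for i, img in enumerate(x):
            feats[i] = hog(rgb2gray(img), orientations=HOG_ORIENTATIONS,
                           pixels_per_cell=HOG_PIXELS_PER_CELL,
                           cells_per_block=HOG_CELLS_PER_BLOCK,
                           block_norm="L2-Hys", feature_vector=True)
        return feats

    def fit(self, train: PatchDataset) -> "HogSvmClassifier":
        _, y = train.as_arrays()
        if y.min() == y.max():
            raise ValueError("training set must contain both classes")
        feats = self.descriptors(train)
        assert feats.shape[1] == HOG_DESCRIPTOR_LENGTH
        self.svm.fit(feats, y)
        self.fitted = True
        return self

    def predict_confidence(self, patches):
        if not self.fitted:
            raise RuntimeError("HOG+SVM baseline has not been fitted")
        single = isinstance(patches, Patch) or (
            isinstance(patches, np.ndarray) and np.asarray(patches).ndim == 3
        )
        margin = self.svm.decision_function(self.descriptors(patches))
        conf = 1.0 / (1.0 + np.exp(-margin))
        return float(conf[0]) if single else conf


def hog_svm_classifier(train: PatchDataset, c: float = 1.0) -> HogSvmClassifier:
    return HogSvmClassifier(c=c).fit(train)


# ---------------------------------------------------------------------------
# metrics


def classification_metrics(labels, predictions) -> ClassificationMetrics:
    """Confusion counts, accuracy and kernel-class F-score.

    ``fp`` counts non-kernels predicted as kernel, ``fn`` kernels predicted
    as non-kernel; accuracy = (n - fp - fn) / n.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("labels and predictions must be equal-length 1-D, n >= 1")
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    tp = int(((p == 1) & (y == 1)).sum())
    n = len(y)
    accuracy = (n - fp - fn) / n
    if tp == 0 and fp == 0 and fn == 0:
        warnings.warn("no positive labels or predictions; F-score defined as 0")
        f_score = 0.0
    elif tp == 0:
        f_score = 0.0
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f_score = 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(fp=fp, fn=fn, accuracy=accuracy, f_score=f_score, n=n)
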
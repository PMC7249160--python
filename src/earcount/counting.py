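"""End-to-end kernel counting.

Pipeline per image: score all sliding windows with the classifier ->
greedy NMS -> regress a kernel center inside each kept window -> map the
centers to image coordinates -> extrapolate the visible-side detection
count to a whole-ear estimate.  Farmers treat ears as symmetric and double
the one-side count; a 180-degree photo additionally misses roughly two
columns on each silhouette edge, which is why the default extrapolation
factor is 2.5 rather than 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .detection import NmsConfig, ScoredBox, extract_window_patches, nms, score_windows
from .regressor import center_to_image_coords, predict_center
from .synthetic import AnnotatedImage

__all__ = [
    "CountingConfig",
    "CountEstimate",
    "CountMetrics",
    "extrapolate_total",
    "count_kernels",
    "count_metrics",
]

DEFAULT_FACTOR = 2.5


@dataclass(frozen=True)
class CountingConfig:
    nms: NmsConfig = field(default_factory=NmsConfig)
    factor: float = DEFAULT_FACTOR

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("extrapolation factor must be positive")


@dataclass
class CountEstimate:
    n_detected: int  # post-NMS kernel windows (visible side)
    factor: float
    total: int  # extrapolated whole-ear estimate
    centers: np.ndarray  # (n_detected, 2) regressed centers, image coords
    boxes: list[ScoredBox] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"n_detected": self.n_detected, "factor": self.factor,
                "total": self.total,
                "centers": [[float(x), float(y)] for x, y in self.centers]}


@dataclass(frozen=True)
class CountMetrics:
    rmse: float
    mae: float
    correlation: float  # Pearson r in [-1, 1]

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "correlation": self.correlation}


def extrapolate_total(n_detected: int, factor: float = DEFAULT_FACTOR) -> int:
    """Whole-ear estimate: factor x one-side count, rounded half away from
    zero (252.5 -> 253)."""
    if n_detected < 0:
        raise ValueError("detection count cannot be negative")
    if factor <= 0:
        raise ValueError("factor must be positive")
    return int(np.floor(factor * n_detected + 0.5))


def count_kernels(image, classifier: nn.Network, regressor: nn.Network,
                  config: CountingConfig = CountingConfig()) -> CountEstimate:
    """Run the full detect-prune-regress-extrapolate pipeline on one image."""
    if not regressor.meta.get("trained"):
        raise RuntimeError("regressor has not been trained or loaded")
    pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image)
    scored = score_windows(classifier, pixels, config.nms)
    kept = nms(scored, config.nms.overlap_threshold)
    if kept:
        origins = [(int(b.x), int(b.y)) for b in kept]
        patches = extract_window_patches(pixels, origins, config.nms.window)
        patch_xy = predict_center(regressor, patches)
        centers = np.array([
            center_to_image_coords((float(px), float(py)), box)
            for (px, py), box in zip(patch_xy, kept)
        ])
    else:
        centers = np.empty((0, 2))
    n_detected = len(kept)
    return CountEstimate(
        n_detected=n_detected,
        factor=config.factor,
        total=extrapolate_total(n_detected, config.factor),
        centers=centers,
        boxes=kept,
    )


def count_metrics(predicted, actual) -> CountMetrics:
    """RMSE, MAE and Pearson correlation between predicted and true counts.

    The correlation is returned on the [-1, 1] scale (conventionally
    displayed x100); it requires n >= 2 and non-zero variance on both
    sides.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError("predicted and actual must be equal-length 1-D")
    if len(p) < 2:
        raise ValueError("need at least two count pairs")
    if p.std() == 0 or a.std() == 0:
        raise ValueError("correlation undefined for zero-variance counts")
    err = p - a
    return CountMetrics(
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        correlation=float(np.corrcoef(p, a)[0, 1]),
    )
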
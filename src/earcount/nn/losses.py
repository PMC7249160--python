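"""Losses: binary cross-entropy on logits and the smooth-L1 (Huber) form."""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "bce_with_logits", "smooth_l1", "smooth_l1_grad"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy (log loss) and its gradient w.r.t. logits.

    Evaluated in the numerically stable log-sum-exp form.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(logits) - targets.astype(logits.dtype)) / logits.shape[0]
    return float(loss.mean()), grad.astype(np.float32)


def smooth_l1(residual: np.ndarray) -> np.ndarray:
    """Elementwise smooth-L1: 0.5 d^2 for |d| < 1, |d| - 0.5 otherwise."""
    residual = np.asarray(residual, dtype=np.float64)
    if not np.all(np.isfinite(residual)):
        raise ValueError("smooth-L1 residual must be finite")
    a = np.abs(residual)
    return np.where(a < 1.0, 0.5 * residual**2, a - 0.5)


def smooth_l1_grad(residual: np.ndarray) -> np.ndarray:
    """d/dd of the elementwise smooth-L1: d for |d| < 1, sign(d) otherwise."""
    residual = np.asarray(residual)
    return np.clip(residual, -1.0, 1.0)
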
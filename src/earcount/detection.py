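"""Sliding-window kernel detection: window enumeration, CNN scoring,
intersection-over-union, and greedy non-maximum suppression.

The scan uses a 32 (tall) x 22 (wide) window — kernels on an ear are taller
than wide — stepped at a configurable stride.  Each window crop is
bilinearly rescaled to the classifier's fixed 32x32 input and scored;
windows below the confidence threshold are dropped and the survivors are
pruned greedily: keep the highest-confidence box, delete every remaining
box whose IOU with it exceeds the overlap threshold, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import nn
from .patches import PATCH_SIZE
from .synthetic import AnnotatedImage

__all__ = [
    "ScoredBox",
    "NmsConfig",
    "enumerate_windows",
    "extract_window_patches",
    "score_windows",
    "iou",
    "nms",
]


@dataclass(frozen=True)
class ScoredBox:
    x: float
    y: float
    width: float
    height: float
    confidence: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box must have positive width and height")
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class NmsConfig:
    overlap_threshold: float = 0.3  # lambda; boxes with IOU > lambda are pruned
    confidence_threshold: float = 0.5
    stride: tuple[int, int] = (4, 4)  # (vertical, horizontal)
    window: tuple[int, int] = (32, 22)  # (height, width)

    def __post_init__(self):
        if not 0 <= self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in [0, 1]")
        if self.stride[0] < 1 or self.stride[1] < 1:
            raise ValueError("strides must be >= 1")


def enumerate_windows(image_size: tuple[int, int], window: tuple[int, int],
                      stride: tuple[int, int]) -> list[tuple[int, int]]:
    """(x, y) origins of all fully-contained windows, row-major order.

    A window larger than the image yields an empty list.
    """
    big_h, big_w = image_size
    win_h, win_w = window
    s_y, s_x = stride
    if s_y < 1 or s_x < 1:
        raise ValueError("strides must be >= 1")
    if win_h > big_h or win_w > big_w:
        return []
    xs = range(0, big_w - win_w + 1, s_x)
    ys = range(0, big_h - win_h + 1, s_y)
    return [(x, y) for y in ys for x in xs]


def _resize_width_weights(src_w: int, dst_w: int):
    """Bilinear sample positions for a 1-D resize (align-corners=False)."""
    xs = (np.arange(dst_w) + 0.5) * src_w / dst_w - 0.5
    lo = np.clip(np.floor(xs).astype(int), 0, src_w - 1)
    hi = np.clip(lo + 1, 0, src_w - 1)
    frac = np.clip(xs - lo, 0.0, 1.0).astype(np.float32)
    return lo, hi, frac


def extract_window_patches(pixels: np.ndarray, origins, window: tuple[int, int]) -> np.ndarray:
    """Cut all windows and rescale each to the 32x32 classifier input.

    Returns float32 (N, 32, 32, 3) in [0, 1].  All windows share one
    geometry, so the bilinear rescale is vectorised across windows.
    """
    win_h, win_w = window
    origins = np.asarray(list(origins), dtype=int).reshape(-1, 2)
    n = len(origins)
    out = np.empty((n, PATCH_SIZE, PATCH_SIZE, 3), dtype=np.float32)
    if n == 0:
        return out
    view = sliding_window_view(pixels, (win_h, win_w), axis=(0, 1))  # (Hs, Ws, 3, h, w)
    ylo, yhi, yfr = _resize_width_weights(win_h, PATCH_SIZE)
    xlo, xhi, xfr = _resize_width_weights(win_w, PATCH_SIZE)
    chunk = 2048
    for i in range(0, n, chunk):
        sel = origins[i : i + chunk]
        crops = view[sel[:, 1], sel[:, 0]].astype(np.float32)  # (m, 3, h, w)
        rows = crops[:, :, ylo, :] * (1 - yfr)[None, None, :, None] \
            + crops[:, :, yhi, :] * yfr[None, None, :, None]
        full = rows[:, :, :, xlo] * (1 - xfr) + rows[:, :, :, xhi] * xfr
        out[i : i + chunk] = full.transpose(0, 2, 3, 1) / 255.0
    return out


def score_windows(model: nn.Network, image, config: NmsConfig = NmsConfig(),
                  batch_size: int = 256) -> list[ScoredBox]:
    """Score every sliding window; keep those at or above the confidence
    threshold as :class:`ScoredBox` at their original geometry."""
    if not model.meta.get("trained"):
        raise RuntimeError("classifier has not been trained or loaded")
    pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image)
    origins = enumerate_windows(pixels.shape[:2], config.window, config.stride)
    if not origins:
        return []
    patches = extract_window_patches(pixels, origins, config.window)
    conf = np.concatenate([
        nn.sigmoid(model.forward(patches[i : i + batch_size], train=False)[:, 0])
        for i in range(0, len(patches), batch_size)
    ])
    win_h, win_w = config.window
    return [
        ScoredBox(x=float(x), y=float(y), width=win_w, height=win_h,
                  confidence=float(c))
        for (x, y), c in zip(origins, conf)
        if c >= config.confidence_threshold
    ]


def iou(a, b) -> float:
    """Intersection over union of two axis-aligned boxes.

    Boxes are half-open [x, x+w) x [y, y+h) on continuous coordinates; the
    result is symmetric and lies in [0, 1].
    """
    for box in (a, b):
        if box.width <= 0 or box.height <= 0:
            raise ValueError("boxes must have positive area")
    ix = min(a.x + a.width, b.x + b.width) - max(a.x, b.x)
    iy = min(a.y + a.height, b.y + b.height) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms(boxes: list[ScoredBox], overlap_threshold: float) -> list[ScoredBox]:
    """Greedy non-maximum suppression.

    Repeatedly keep the highest-confidence remaining box and delete every
    remaining box with IOU strictly greater than the threshold against it
    (a box at exactly the threshold survives).  Ties on confidence break by
    smaller (y, x) origin, then input index, so the result does not depend
    on input order.  Kept boxes are returned in selection order.
    """
    if not 0 <= overlap_threshold <= 1:
        raise ValueError("overlap threshold must be in [0, 1]")
    if not boxes:
        return []
    order = sorted(range(len(boxes)),
                   key=lambda i: (-boxes[i].confidence, boxes[i].y, boxes[i].x, i))
    arr = np.array([[b.x, b.y, b.x + b.width, b.y + b.height,
                     b.width * b.height] for b in boxes], dtype=float)[order]
    alive = np.ones(len(order), dtype=bool)
    kept: list[ScoredBox] = []
    for i in range(len(order)):
        if not alive[i]:
            continue
        kept.append(boxes[order[i]])
        alive[i] = False
        rest = np.flatnonzero(alive)
        if not len(rest):
            break
        ix = np.minimum(arr[rest, 2], arr[i, 2]) - np.maximum(arr[rest, 0], arr[i, 0])
        iy = np.minimum(arr[rest, 3], arr[i, 3]) - np.maximum(arr[rest, 1], arr[i, 1])
        inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
        overlap = inter / (arr[rest, 4] + arr[i, 4] - inter)
        alive[rest[overlap > overlap_threshold]] = False
    return kept
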
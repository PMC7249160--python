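"""Construction of the 32x32 patch datasets that train the classifier and
the center regressor.

Labeling rule: a crop showing exactly one kernel is a positive sample; a
crop with zero or with two or more kernel centers is a negative sample.
Candidate negative crops that happen to contain exactly one center are
rejected and resampled, so the rule is total.  Positive crops are the
ground-truth kernel box dilated by a small margin, rescaled to 32x32 with
the annotated center mapped through the same transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .synthetic import AnnotatedImage

__all__ = [
    "Patch",
    "PatchDataset",
    "SamplingError",
    "extract_positive_patches",
    "extract_negative_patches",
    "augment_patches",
    "split_dataset",
]

PATCH_SIZE = 32

KERNEL = "kernel"
NON_KERNEL = "non_kernel"


class SamplingError(RuntimeError):
    """Could not find enough qualifying crops within the draw budget."""


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(eq=False)
class Patch:
    """A 32x32 RGB crop with a binary label and, for positives, the
    in-patch kernel center in continuous patch coordinates [0, 32)."""

    pixels: np.ndarray
    label: str
    center: tuple[float, float] | None = None
    source: str = ""
    origin: tuple[int, int] = (0, 0)  # crop origin (x, y) in the source image
    crop_size: tuple[int, int] | None = None  # source crop (width, height)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(f"patch pixels must be {PATCH_SIZE}x{PATCH_SIZE}x3")
        if self.label not in (KERNEL, NON_KERNEL):
            raise ValueError(f"unknown label {self.label!r}")
        if self.center is not None:
            if self.label != KERNEL:
                raise ValueError("only kernel patches carry a center")
            x, y = self.center
            if not (0 <= x < PATCH_SIZE and 0 <= y < PATCH_SIZE):
                raise ValueError("center must lie in [0, 32) x [0, 32)")


@dataclass
class PatchDataset:
    patches: list[Patch] = field(default_factory=list)
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def class_counts(self) -> dict[str, int]:
        counts = {KERNEL: 0, NON_KERNEL: 0}
        for p in self.patches:
            counts[p.label] += 1
        return counts

    def positives(self) -> "PatchDataset":
        return PatchDataset([p for p in self.patches if p.label == KERNEL], self.rng_seed)

    def as_arrays(self, with_centers: bool = False):
        """(X, y[, centers]) arrays; X is float32 in [0, 1], NHWC."""
        x = np.stack([p.pixels for p in self.patches]).astype(np.float32) / 255.0
        y = np.array([1.0 if p.label == KERNEL else 0.0 for p in self.patches],
                     dtype=np.float32)
        if not with_centers:
            return x, y
        centers = np.array([p.center if p.center is not None else (np.nan, np.nan)
                            for p in self.patches], dtype=np.float32)
        return x, y, centers

    def extend(self, other: "PatchDataset") -> "PatchDataset":
        return PatchDataset(self.patches + other.patches, self.rng_seed)


def _crop_resized(pixels: np.ndarray, x0: int, y0: int, x1: int, y1: int) -> np.ndarray:
    crop = Image.fromarray(pixels[y0:y1, x0:x1])
    return np.asarray(crop.resize((PATCH_SIZE, PATCH_SIZE), Image.BILINEAR))


def _centers_in_rect(centers: np.ndarray, x0, y0, x1, y1) -> np.ndarray:
    x, y = centers[:, 0], centers[:, 1]
    return (x >= x0) & (x < x1) & (y >= y0) & (y < y1)


def extract_positive_patches(image: AnnotatedImage, margin: float = 2.0,
                             crop_size: tuple[int, int] | None = None,
                             align_stride: tuple[int, int] | None = None,
                             source: str = "") -> list[Patch]:
    """One positive patch per kernel whose crop contains no second kernel
    center; crowded kernels are skipped, never mislabeled.

    By default the crop is the kernel's ground-truth box dilated by
    ``margin`` (hand-cropped-style tight samples).  With ``crop_size``
    (height, width) the crop is instead a fixed window centred on the
    kernel — the distribution the sliding-window detector sees at scan
    time — optionally snapped to a detection stride grid via
    ``align_stride`` (vertical, horizontal).
    """
    if image.boxes is None:
        raise ValueError("positive extraction needs ground-truth boxes")
    h, w = image.shape
    out: list[Patch] = []
    for i, (bx, by, bw, bh) in enumerate(image.boxes):
        if crop_size is not None:
            ch, cw = crop_size
            cx, cy = image.centers[i]
            x0f, y0f = cx - cw / 2, cy - ch / 2
            if align_stride is not None:
                sy, sx = align_stride
                x0 = int(np.clip(round(x0f / sx) * sx, 0, w - cw))
                y0 = int(np.clip(round(y0f / sy) * sy, 0, h - ch))
            else:
                x0 = int(np.clip(round(x0f), 0, w - cw))
                y0 = int(np.clip(round(y0f), 0, h - ch))
            x1, y1 = x0 + cw, y0 + ch
        else:
            x0 = max(int(np.floor(bx - margin)), 0)
            y0 = max(int(np.floor(by - margin)), 0)
            x1 = min(int(np.ceil(bx + bw + margin)), w)
            y1 = min(int(np.ceil(by + bh + margin)), h)
        if x1 - x0 < 2 or y1 - y0 < 2:
            continue
        inside = _centers_in_rect(image.centers, x0, y0, x1, y1)
        if not inside[i] or inside.sum() != 1:
            continue  # the crop would show zero or several kernels
        cx, cy = image.centers[i]
        px = (cx - x0) * PATCH_SIZE / (x1 - x0)
        py = (cy - y0) * PATCH_SIZE / (y1 - y0)
        out.append(Patch(
            pixels=_crop_resized(image.pixels, x0, y0, x1, y1),
            label=KERNEL, center=(px, py), source=source, origin=(x0, y0),
            crop_size=(x1 - x0, y1 - y0),
        ))
    return out


def extract_negative_patches(image: AnnotatedImage, n: int, rng_seed: int = 0,
                             crop_size: tuple[int, int] | None = None,
                             source: str = "") -> list[Patch]:
    """``n`` random crops containing zero or >= 2 kernel centers.

    Crop dimensions are sampled around the scene's typical kernel-box size
    (falling back to ``crop_size`` or 32x22) so negatives match the scale of
    sliding windows.  Raises :class:`SamplingError` if the draw budget is
    exhausted before ``n`` qualifying crops are found.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    h, w = image.shape
    fixed = crop_size is not None
    if fixed:
        base_h, base_w = crop_size
    elif image.boxes is not None and len(image.boxes):
        base_w = float(np.median(image.boxes[:, 2]))
        base_h = float(np.median(image.boxes[:, 3]))
    else:
        base_h, base_w = 32.0, 22.0

    out: list[Patch] = []
    budget = 60 * n
    while len(out) < n and budget > 0:
        budget -= 1
        if fixed:
            ch, cw = int(base_h), int(base_w)
        else:
            ch = int(round(base_h * rng.uniform(0.8, 1.4)))
            cw = int(round(base_w * rng.uniform(0.8, 1.4)))
        ch, cw = max(ch, 4), max(cw, 4)
        if ch > h or cw > w:
            continue
        x0 = int(rng.integers(0, w - cw + 1))
        y0 = int(rng.integers(0, h - ch + 1))
        n_inside = int(_centers_in_rect(image.centers, x0, y0, x0 + cw, y0 + ch).sum())
        if n_inside == 1:
            continue  # would be a (mislabeled) single-kernel crop
        out.append(Patch(
            pixels=_crop_resized(image.pixels, x0, y0, x0 + cw, y0 + ch),
            label=NON_KERNEL, source=source, origin=(x0, y0), crop_size=(cw, ch),
        ))
    if len(out) < n:
        raise SamplingError(f"found only {len(out)}/{n} qualifying negative crops")
    return out


def _jitter_colors(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative brightness/saturation jitter plus a small hue shift."""
    from skimage.color import hsv2rgb, rgb2hsv

    hsv = rgb2hsv(pixels.astype(np.float32) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(-10 / 360, 10 / 360)) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(0.8, 1.2), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(0.8, 1.2), 0, 1)
    return (hsv2rgb(hsv) * 255.0 + 0.5).astype(np.uint8)


def augment_patches(patches: list[Patch], fraction: float = 0.7,
                    rng_seed: int = 0) -> list[Patch]:
    """Append one flip+color-jitter copy for round(fraction * N) patches.

    Originals are retained; the stored kernel center is mirrored
    consistently with the flip (``x -> 32 - x`` under a left-right flip in
    the half-open pixel convention).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    k = _round_half_up(fraction * len(patches))
    chosen = rng.choice(len(patches), size=k, replace=False) if k else []
    augmented = list(patches)
    for idx in sorted(int(i) for i in np.asarray(chosen)):
        p = patches[idx]
        pixels = p.pixels
        cx, cy = p.center if p.center is not None else (None, None)
        flip_h = bool(rng.integers(2))
        flip_v = bool(rng.integers(2))
        if flip_h:
            pixels = pixels[:, ::-1]
            if cx is not None:
                cx = PATCH_SIZE - cx
        if flip_v:
            pixels = pixels[::-1]
            if cy is not None:
                cy = PATCH_SIZE - cy
        pixels = _jitter_colors(np.ascontiguousarray(pixels), rng)
        center = None
        if p.center is not None:
            # a center exactly on the patch edge mirrors onto 32.0; clamp in
            center = (min(cx, np.nextafter(PATCH_SIZE, 0)), min(cy, np.nextafter(PATCH_SIZE, 0)))
        augmented.append(Patch(pixels=pixels, label=p.label, center=center,
                               source=p.source, origin=p.origin, crop_size=p.crop_size))
    return augmented


def split_dataset(dataset: PatchDataset, test_fraction: float,
                  rng_seed: int = 0) -> tuple[PatchDataset, PatchDataset]:
    """Seed-deterministic uniform train/test partition.

    ``|test| = round(test_fraction * |dataset|)`` with round-to-nearest
    (half up); raises ``ValueError`` if either side would be empty.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(dataset)
    n_test = _round_half_up(test_fraction * n)
    if n_test == 0 or n_test == n:
        raise ValueError("split would leave an empty train or test set")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [dataset.patches[i] for i in range(n) if i not in test_idx]
    test = [dataset.patches[i] for i in sorted(order[:n_test].tolist())]
    return (PatchDataset(train, rng_seed), PatchDataset(test, rng_seed))
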
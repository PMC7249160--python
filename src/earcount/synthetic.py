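"""Procedural generation of annotated corn-ear images.

Real ear photographs show a few hundred near-touching kernels packed in
columns on the camera-facing side of the ear, at varied ear angles, in
uncontrolled lighting, over soil/grass/hand backgrounds.  No public image
set with kernel-level annotations exists, so this module renders scenes
with that statistical structure and exact ground truth: every rendered
kernel contributes one sub-pixel center and one tight bounding box.

Geometry.  An ear is modelled as a tapered cylinder seen from one side.
Kernel columns sit at equal arc spacing around the cylinder; only the
columns within +/-72 degrees of the camera axis are rendered and annotated,
i.e. 40% of the full circumference.  That makes the field's x2.5
"visible side to whole ear" extrapolation the geometric truth of a scene:
the whole-ear ground-truth count is ``round(2.5 * visible_columns) * rows``.
Foreshortening compresses and darkens columns near the silhouette edges,
rows of adjacent columns are staggered by half a pitch (as on real ears),
and the ear tapers toward tip and butt.

Coordinates are continuous, 0-based, x = column and y = row, origin at the
top-left corner; pixel (i, j) covers the unit square [j, j+1) x [i, i+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

__all__ = [
    "EarSceneParams",
    "EarAnnotation",
    "AnnotatedImage",
    "PlacementError",
    "BACKGROUND_CLASSES",
    "render_ear_image",
    "render_batch_scene",
]

BACKGROUND_CLASSES = ("soil", "grass", "hand", "plain")

# Lattice constants, in units of the kernel radius parameter r (the kernel
# half-width).  Chosen so kernels nearly touch along rows and columns while
# every pair of centers stays at least one radius apart even under jitter.
VISIBLE_HALF_ANGLE = 0.4 * math.pi  # 72 deg; visible arc = 40% of circle
COLUMN_ARC = 2.0  # surface arc between adjacent columns
ROW_PITCH = 3.0  # vertical distance between rows of one column
KERNEL_HALF_HEIGHT = 1.25  # vertical semi-axis of a kernel ellipse
TAPER_MIN = 0.9  # lattice/kernel shrink factor at ear tip and butt
JITTER_CLAMP_FRAC = 0.2  # max jitter displacement as a fraction of r
MIN_FORESHORTEN = 0.25

_BG_TINT = {
    "soil": (118, 86, 58),
    "grass": (62, 112, 48),
    "hand": (196, 146, 112),
    "plain": (205, 205, 200),
}


class PlacementError(RuntimeError):
    """Ears could not be placed without overlap at the requested sizes."""


@dataclass(frozen=True)
class EarSceneParams:
    """Scene configuration; defaults emulate 768x1024 single-ear photos."""

    image_size: tuple[int, int] = (1024, 768)  # (height, width)
    n_ears: int = 1
    kernels_per_column: tuple[int, int] = (15, 26)
    visible_columns: tuple[int, int] = (10, 14)
    kernel_radius: tuple[float, float] = (8.0, 11.0)
    ear_tilt: tuple[float, float] = (-20.0, 20.0)  # degrees
    lighting_gain: tuple[float, float] = (0.75, 1.2)
    background_class: str | None = None  # None: sample per scene
    jitter: float = 0.7  # std-dev of kernel position noise, px
    rng_seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError("image dimensions must be at least 64x64")
        if self.n_ears < 1:
            raise ValueError("n_ears must be >= 1")
        if self.kernel_radius[0] < 3:
            raise ValueError("kernel_radius must be >= 3 px")
        for name in ("kernels_per_column", "visible_columns", "kernel_radius",
                     "ear_tilt", "lighting_gain"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must satisfy low <= high")
        if self.background_class is not None and self.background_class not in BACKGROUND_CLASSES:
            raise ValueError(f"background_class must be one of {BACKGROUND_CLASSES}")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


@dataclass
class EarAnnotation:
    """Per-ear bookkeeping inside a scene."""

    center_slice: tuple[int, int]  # [start, stop) into the scene center list
    n_visible: int
    n_total: int  # whole-ear kernel count, hidden side included
    bbox: tuple[float, float, float, float]  # x0, y0, x1, y1
    tilt_deg: float
    radius: float
    rows: int
    columns: int


@dataclass(eq=False)
class AnnotatedImage:
    """An RGB scene with ground-truth kernel centers and boxes."""

    pixels: np.ndarray  # H x W x 3 uint8
    centers: np.ndarray  # N x 2 float, (x, y)
    boxes: np.ndarray | None = None  # N x 4 float, (x, y, w, h)
    ears: list[EarAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        h, w = self.pixels.shape[:2]
        if len(self.centers):
            x, y = self.centers[:, 0], self.centers[:, 1]
            if (x < 0).any() or (x >= w).any() or (y < 0).any() or (y >= h).any():
                raise ValueError("annotation centers must lie inside the image")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float).reshape(-1, 4)
            if len(self.boxes) != len(self.centers):
                raise ValueError("need exactly one box per center")
            bx, by, bw, bh = self.boxes.T
            inside = (
                (self.centers[:, 0] >= bx) & (self.centers[:, 0] <= bx + bw)
                & (self.centers[:, 1] >= by) & (self.centers[:, 1] <= by + bh)
            )
            if len(self.boxes) and not inside.all():
                raise ValueError("each center must lie inside its box")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def total_kernels(self) -> int:
        """Whole-ear ground truth summed over ears (hidden side included)."""
        return sum(e.n_total for e in self.ears)

    def ear_centers(self, index: int) -> np.ndarray:
        start, stop = self.ears[index].center_slice
        return self.centers[start:stop]


# ---------------------------------------------------------------------------
# lattice


def _ear_lattice(rng: np.random.Generator, rows: int, cols: int, radius: float,
                 jitter: float):
    """Kernel centers/axes for one untilted ear in ear-local coordinates."""
    thv = VISIBLE_HALF_ANGLE
    r_cyl = cols * COLUMN_ARC * radius / (2 * thv)
    theta = -thv + (np.arange(cols) + 0.5) * (2 * thv / cols)
    fs = np.maximum(np.cos(theta), MIN_FORESHORTEN)
    col_x = r_cyl * np.sin(theta)

    pitch = ROW_PITCH * radius
    length = (rows + 0.5) * pitch  # +0.5 for the stagger overhang
    xs, ys, axes_a, axes_b, shade = [], [], [], [], []
    for c in range(cols):
        stagger = 0.5 * pitch if c % 2 else 0.0
        for i in range(rows):
            y = (i + 0.5) * pitch + stagger - length / 2
            t = (y + length / 2) / length
            m = TAPER_MIN + (1 - TAPER_MIN) * math.sin(math.pi * min(max(t, 0.0), 1.0))
            xs.append(col_x[c] * m)
            ys.append(y)
            axes_a.append(0.98 * radius * fs[c] * m)
            axes_b.append(KERNEL_HALF_HEIGHT * radius * m)
            shade.append(0.45 + 0.55 * fs[c])
    xs = np.array(xs)
    ys = np.array(ys)

    if jitter > 0:
        clamp = min(2.5 * jitter, JITTER_CLAMP_FRAC * radius)
        d = rng.normal(0.0, jitter, size=(len(xs), 2))
        norm = np.linalg.norm(d, axis=1)
        over = norm > clamp
        d[over] *= (clamp / norm[over])[:, None]
        xs = xs + d[:, 0]
        ys = ys + d[:, 1]

    half_width = r_cyl * math.sin(thv) + 1.1 * radius
    half_length = length / 2 + KERNEL_HALF_HEIGHT * radius
    return xs, ys, np.array(axes_a), np.array(axes_b), np.array(shade), half_width, half_length


def _rotate(xs, ys, tilt_rad):
    c, s = math.cos(tilt_rad), math.sin(tilt_rad)
    return xs * c - ys * s, xs * s + ys * c


# ---------------------------------------------------------------------------
# rasterisation


def _hsv_to_rgb(h, s, v):
    h = h % 1.0
    i = int(h * 6)
    f = h * 6 - i
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    return [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i % 6]


def _fill_background(img: np.ndarray, rng: np.random.Generator, bg_class: str) -> None:
    h, w = img.shape[:2]
    tint = np.array(_BG_TINT[bg_class], dtype=float)
    coarse = rng.uniform(-1, 1, size=(max(h // 48, 2), max(w // 48, 2)))
    noise = resize(coarse, (h, w), order=1, mode="edge", anti_aliasing=False)
    img[...] = tint * (1.0 + 0.25 * noise)[..., None]
    img += rng.uniform(-8, 8, size=(h, w, 1))


def _draw_capsule(img, p0, p1, half_width, color, rng):
    """Filled rounded-end bar (the cob silhouette behind the kernels)."""
    h, w = img.shape[:2]
    x0 = max(int(min(p0[0], p1[0]) - half_width) - 1, 0)
    x1 = min(int(max(p0[0], p1[0]) + half_width) + 2, w)
    y0 = max(int(min(p0[1], p1[1]) - half_width) - 1, 0)
    y1 = min(int(max(p0[1], p1[1]) + half_width) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    px = xx + 0.5
    py = yy + 0.5
    d = np.array(p1) - np.array(p0)
    denom = float(d @ d) or 1.0
    t = np.clip(((px - p0[0]) * d[0] + (py - p0[1]) * d[1]) / denom, 0, 1)
    dist = np.hypot(px - (p0[0] + t * d[0]), py - (p0[1] + t * d[1]))
    mask = dist <= half_width
    region = img[y0:y1, x0:x1]
    texture = 1.0 + rng.uniform(-0.06, 0.06, size=mask.sum())[:, None]
    region[mask] = np.array(color) * texture


def _draw_kernel(img, cx, cy, a, b, angle, hue, sat, val):
    h, w = img.shape[:2]
    cos_t, sin_t = math.cos(angle), math.sin(angle)
    ex = math.hypot(a * cos_t, b * sin_t)
    ey = math.hypot(a * sin_t, b * cos_t)
    x0 = max(int(cx - ex) - 1, 0)
    x1 = min(int(cx + ex) + 2, w)
    y0 = max(int(cy - ey) - 1, 0)
    y1 = min(int(cy + ey) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx + 0.5 - cx
    dy = yy + 0.5 - cy
    u = (dx * cos_t + dy * sin_t) / a
    v = (-dx * sin_t + dy * cos_t) / b
    d2 = u * u + v * v
    mask = d2 <= 1.0
    if not mask.any():
        return
    base = np.array(_hsv_to_rgb(hue, sat, 1.0)) * 255.0
    # radial shading plus an off-center specular highlight
    radial = 1.0 - 0.40 * d2[mask]
    highlight = 0.30 * np.exp(-(((u[mask] + 0.30) ** 2) + ((v[mask] + 0.30) ** 2)) / 0.18)
    img[y0:y1, x0:x1][mask] = base * (val * (radial + highlight))[:, None]


# ---------------------------------------------------------------------------
# scene assembly


def _sample_ear(rng: np.random.Generator, params: EarSceneParams):
    rows = int(rng.integers(params.kernels_per_column[0], params.kernels_per_column[1] + 1))
    cols = int(rng.integers(params.visible_columns[0], params.visible_columns[1] + 1))
    radius = float(rng.uniform(*params.kernel_radius))
    tilt = float(rng.uniform(*params.ear_tilt))
    return rows, cols, radius, tilt


def render_ear_image(params: EarSceneParams) -> AnnotatedImage:
    """Render one scene (one or more ears) with exact annotations.

    Deterministic for a fixed ``params.rng_seed``.  Raises ``ValueError``
    when a single ear cannot fit the image at the requested kernel radius,
    and :class:`PlacementError` when several ears cannot be placed without
    overlap after bounded retries.
    """
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_size
    img = np.empty((h, w, 3), dtype=float)
    bg = params.background_class or BACKGROUND_CLASSES[int(rng.integers(len(BACKGROUND_CLASSES)))]
    _fill_background(img, rng, bg)

    slot_w = w / params.n_ears
    margin = 2.0
    centers: list[np.ndarray] = []
    boxes: list[np.ndarray] = []
    ears: list[EarAnnotation] = []

    for e in range(params.n_ears):
        placed = False
        for _ in range(40):
            rows, cols, radius, tilt = _sample_ear(rng, params)
            xs, ys, aa, bb, shade, half_w, half_l = _ear_lattice(rng, rows, cols, radius, params.jitter)
            tilt_rad = math.radians(tilt)
            # rotated extents of the ear envelope
            ext_x = half_w * abs(math.cos(tilt_rad)) + half_l * abs(math.sin(tilt_rad))
            ext_y = half_w * abs(math.sin(tilt_rad)) + half_l * abs(math.cos(tilt_rad))
            if 2 * ext_x + 2 * margin > slot_w or 2 * ext_y + 2 * margin > h:
                continue
            slack_x = slot_w / 2 - ext_x - margin
            slack_y = h / 2 - ext_y - margin
            cx = slot_w * (e + 0.5) + rng.uniform(-slack_x, slack_x)
            cy = h / 2 + rng.uniform(-slack_y, slack_y)
            placed = True
            break
        if not placed:
            if params.n_ears == 1:
                raise ValueError(
                    "image too small to contain one ear at the requested kernel radius"
                )
            raise PlacementError(
                "ears cannot be placed without overlap at the requested sizes"
            )

        rx, ry = _rotate(xs, ys, tilt_rad)
        kx, ky = rx + cx, ry + cy

        # cob silhouette behind the kernels
        axis_x, axis_y = _rotate(np.array([0.0, 0.0]), np.array([-half_l, half_l]), tilt_rad)
        cob = np.array(_hsv_to_rgb(0.09, 0.75, 0.45)) * 255.0
        _draw_capsule(img, (axis_x[0] + cx, axis_y[0] + cy), (axis_x[1] + cx, axis_y[1] + cy),
                      half_w * 0.98, cob, rng)

        hue = rng.normal(0.125, 0.012, size=len(kx))
        sat = np.clip(rng.normal(0.80, 0.05, size=len(kx)), 0.5, 0.95)
        val = np.clip(shade * rng.normal(1.0, 0.06, size=len(kx)), 0.25, 1.0)
        order = np.argsort(ky)  # draw top rows first
        for idx in order:
            _draw_kernel(img, kx[idx], ky[idx], aa[idx], bb[idx], tilt_rad,
                         float(hue[idx]), float(sat[idx]), float(val[idx]))

        cos_t, sin_t = abs(math.cos(tilt_rad)), abs(math.sin(tilt_rad))
        ex = np.hypot(aa * cos_t, bb * sin_t)
        ey = np.hypot(aa * sin_t, bb * cos_t)
        start = sum(len(c) for c in centers)
        centers.append(np.column_stack([kx, ky]))
        boxes.append(np.column_stack([kx - ex, ky - ey, 2 * ex, 2 * ey]))
        ears.append(EarAnnotation(
            center_slice=(start, start + len(kx)),
            n_visible=len(kx),
            n_total=int(round(2 * math.pi / (2 * VISIBLE_HALF_ANGLE / cols))) * rows,
            bbox=(cx - ext_x, cy - ext_y, cx + ext_x, cy + ext_y),
            tilt_deg=tilt, radius=radius, rows=rows, columns=cols,
        ))

    gain = rng.uniform(*params.lighting_gain)
    pixels = np.clip(img * gain, 0, 255).astype(np.uint8)
    all_centers = np.concatenate(centers) if centers else np.empty((0, 2))
    all_boxes = np.concatenate(boxes) if boxes else np.empty((0, 4))
    return AnnotatedImage(pixels=pixels, centers=all_centers, boxes=all_boxes, ears=ears)


def render_batch_scene(params: EarSceneParams) -> AnnotatedImage:
    """Render a multi-ear scene (n_ears >= 2) with disjoint ear regions."""
    if params.n_ears < 2:
        raise ValueError("render_batch_scene requires n_ears >= 2")
    return render_ear_image(params)
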
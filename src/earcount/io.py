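"""Readers and writers for the artifacts the pipeline touches.

Annotation dialects: a minimal CSV (header ``image,x,y``, one kernel center
per row) and LabelMe-style JSON (one ``point`` shape per kernel).  Both
normalise to the same structure: a mapping from image name to an (N, 2)
array of (x, y) centers in the 0-based, x = column / y = row convention.
Malformed inputs raise, naming the offending record; readers never repair.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .patches import Patch, PatchDataset

__all__ = [
    "read_annotations",
    "write_annotations_csv",
    "write_annotations_labelme",
    "write_detections_csv",
    "render_overlay",
    "save_patch_dataset",
    "load_patch_dataset",
    "write_sidecar",
]

BOX_COLOR = (0, 0, 255)  # blue boxes for kernel-classified windows
DOT_COLOR = (0, 0, 255)  # blue dot at each regressed kernel center


class AnnotationError(ValueError):
    pass


def _parse_center(image: str, x: str, y: str, where: str) -> tuple[float, float]:
    try:
        return float(x), float(y)
    except ValueError as exc:
        raise AnnotationError(f"{where}: non-numeric center for {image!r}") from exc


def read_annotations(path: str | Path, dialect: str | None = None) -> dict[str, np.ndarray]:
    """Per-image center arrays from CSV or LabelMe-style JSON.

    ``dialect`` is ``"csv"`` or ``"labelme_json"``; by default it is taken
    from the file suffix.
    """
    path = Path(path)
    if dialect is None:
        dialect = "labelme_json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "labelme_json":
        return _read_labelme(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_csv(path: Path) -> dict[str, np.ndarray]:
    out: dict[str, list] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if lineno == 1 and [c.strip().lower() for c in row] == ["image", "x", "y"]:
                continue
            if len(row) != 3:
                raise AnnotationError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            image, x, y = (c.strip() for c in row)
            out.setdefault(image, []).append(_parse_center(image, x, y, f"{path}:{lineno}"))
    return {k: np.array(v, dtype=float) for k, v in out.items()}


def _read_labelme(path: Path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"{path}: invalid JSON ({exc})") from exc
    docs = doc if isinstance(doc, list) else [doc]
    out: dict[str, list] = {}
    for rec_no, rec in enumerate(docs):
        image = rec.get("imagePath")
        if not image:
            raise AnnotationError(f"{path}: record {rec_no} missing imagePath")
        pts = out.setdefault(image, [])
        for shape_no, shape in enumerate(rec.get("shapes", [])):
            if shape.get("shape_type") != "point":
                continue
            points = shape.get("points") or []
            if len(points) != 1 or len(points[0]) != 2:
                raise AnnotationError(
                    f"{path}: record {rec_no} shape {shape_no}: a point shape "
                    "needs exactly one (x, y) pair")
            pts.append((float(points[0][0]), float(points[0][1])))
    return {k: np.array(v, dtype=float).reshape(-1, 2) for k, v in out.items()}


def write_annotations_csv(path: str | Path, annotations: dict[str, np.ndarray]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "x", "y"])
        for image in annotations:
            for x, y in np.asarray(annotations[image]).reshape(-1, 2):
                writer.writerow([image, repr(float(x)), repr(float(y))])


def write_annotations_labelme(path: str | Path, image: str,
                              centers: np.ndarray,
                              image_size: tuple[int, int] | None = None) -> None:
    """One LabelMe-style document with a point shape per kernel."""
    doc = {
        "version": "5.0.1",
        "flags": {},
        "imagePath": image,
        "imageData": None,
        "shapes": [
            {"label": "kernel", "points": [[float(x), float(y)]],
             "group_id": None, "shape_type": "point", "flags": {}}
            for x, y in np.asarray(centers).reshape(-1, 2)
        ],
    }
    if image_size is not None:
        doc["imageHeight"], doc["imageWidth"] = int(image_size[0]), int(image_size[1])
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_detections_csv(path: str | Path, boxes) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "width", "height", "confidence"])
        for b in boxes:
            writer.writerow([b.x, b.y, b.width, b.height, b.confidence])


def render_overlay(image, boxes=None, centers=None,
                   out_path: str | Path | None = None) -> np.ndarray:
    """Burn detection boxes (1-px blue borders) and/or center dots into a
    copy of the image; the source is never mutated."""
    pixels = np.array(image.pixels if hasattr(image, "pixels") else image,
                      dtype=np.uint8, copy=True)
    h, w = pixels.shape[:2]
    for b in boxes or []:
        x0, y0 = int(round(b.x)), int(round(b.y))
        x1 = min(int(round(b.x + b.width)), w)
        y1 = min(int(round(b.y + b.height)), h)
        x0, y0 = max(x0, 0), max(y0, 0)
        if x1 <= x0 or y1 <= y0:
            continue
        pixels[y0, x0:x1] = BOX_COLOR
        pixels[y1 - 1, x0:x1] = BOX_COLOR
        pixels[y0:y1, x0] = BOX_COLOR
        pixels[y0:y1, x1 - 1] = BOX_COLOR
    if centers is not None:
        for cx, cy in np.asarray(centers).reshape(-1, 2):
            ix, iy = int(cx), int(cy)
            ys = slice(max(iy - 1, 0), min(iy + 2, h))
            xs = slice(max(ix - 1, 0), min(ix + 2, w))
            pixels[ys, xs] = DOT_COLOR
    if out_path is not None:
        Image.fromarray(pixels).save(out_path)
    return pixels


# ---------------------------------------------------------------------------
# patch-dataset persistence


def save_patch_dataset(dataset: PatchDataset, directory: str | Path) -> Path:
    """PNG patches plus a CSV manifest (file, label, center_x, center_y)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "label", "center_x", "center_y"])
        for i, p in enumerate(dataset.patches):
            name = f"patch_{i:06d}.png"
            Image.fromarray(p.pixels).save(directory / name)
            cx, cy = p.center if p.center is not None else ("", "")
            writer.writerow([name, p.label, cx, cy])
    return manifest


def load_patch_dataset(directory: str | Path) -> PatchDataset:
    directory = Path(directory)
    patches = []
    with open(directory / "manifest.csv", newline="") as fh:
        for rec in csv.DictReader(fh):
            pixels = np.asarray(Image.open(directory / rec["file"]))
            center = None
            if rec["center_x"] != "":
                center = (float(rec["center_x"]), float(rec["center_y"]))
            patches.append(Patch(pixels=pixels, label=rec["label"], center=center,
                                 source=rec["file"]))
    return PatchDataset(patches)


def write_sidecar(artifact_path: str | Path, config: dict, seed: int) -> Path:
    """JSON sidecar recording the config (and its hash) and seed that
    produced an artifact, so any output can be regenerated."""
    payload = json.dumps(config, sort_keys=True, default=str)
    sidecar = Path(str(artifact_path) + ".json")
    with open(sidecar, "w") as fh:
        json.dump({
            "config": config,
            "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
            "rng_seed": seed,
        }, fh, indent=1, default=str)
    return sidecar
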
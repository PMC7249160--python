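"""Window enumeration, IOU, greedy NMS (with an independent oracle), and
window scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earcount.detection import (
    NmsConfig,
    ScoredBox,
    enumerate_windows,
    extract_window_patches,
    iou,
    nms,
    score_windows,
)

# ---------------------------------------------------------------------------
# window enumeration


def test_window_enumeration_count_and_order():
    origins = enumerate_windows((64, 44), (32, 22), (4, 4))
    # 6 x-positions, 9 y-positions, row-major
    assert len(origins) == 54
    assert origins[0] == (0, 0)
    assert origins[1] == (4, 0)
    assert origins[-1] == (20, 32)
    xs = {x for x, _ in origins}
    ys = {y for _, y in origins}
    assert xs == set(range(0, 24, 4)) and ys == set(range(0, 36, 4))


def test_window_exactly_image_sized():
    assert enumerate_windows((32, 22), (32, 22), (4, 4)) == [(0, 0)]


def test_window_larger_than_image_is_empty():
    assert enumerate_windows((31, 44), (32, 22), (4, 4)) == []


# ---------------------------------------------------------------------------
# IOU


def test_iou_identity_disjoint_and_partial():
    a = ScoredBox(0, 0, 2, 2, 0.5)
    b = ScoredBox(1, 1, 2, 2, 0.5)
    c = ScoredBox(10, 10, 2, 2, 0.5)
    assert iou(a, a) == 1.0
    assert iou(a, c) == 0.0
    assert iou(a, b) == pytest.approx(1 / 7, abs=1e-12)


def test_iou_rejects_degenerate_boxes():
    class Box:
        x = y = 0.0
        width = 0.0
        height = 2.0
        area = 0.0

    with pytest.raises(ValueError):
        iou(Box(), ScoredBox(0, 0, 1, 1, 0.5))


@settings(max_examples=300, derandomize=True)
@given(st.tuples(*[st.floats(0, 50) for _ in range(4)],
                 *[st.floats(0.5, 30) for _ in range(4)]))
def test_iou_symmetry_and_bounds(values):
    ax, ay, bx, by, aw, ah, bw, bh = values
    a = ScoredBox(ax, ay, aw, ah, 0.5)
    b = ScoredBox(bx, by, bw, bh, 0.5)
    v = iou(a, b)
    assert 0.0 <= v <= 1.0
    assert v == pytest.approx(iou(b, a), rel=1e-12)


# ---------------------------------------------------------------------------
# NMS against an independent brute-force oracle


def _nms_oracle(boxes, lam):
    """Literal transcription of the pruning procedure with shapely areas."""
    import shapely

    def shapely_iou(a, b):
        pa = shapely.box(a.x, a.y, a.x + a.width, a.y + a.height)
        pb = shapely.box(b.x, b.y, b.x + b.width, b.y + b.height)
        inter = pa.intersection(pb).area
        return inter / (pa.area + pb.area - inter)

    pool = list(boxes)
    kept = []
    while pool:
        # highest confidence; ties by smaller (y, x) then original order
        best = min(pool, key=lambda b: (-b.confidence, b.y, b.x, boxes.index(b)))
        kept.append(best)
        pool.remove(best)
        pool = [b for b in pool if shapely_iou(best, b) <= lam]
    return kept


def _random_boxes(rng, n=200):
    return [
        ScoredBox(
            x=float(rng.uniform(0, 90)), y=float(rng.uniform(0, 90)),
            width=float(rng.uniform(2, 20)), height=float(rng.uniform(2, 20)),
            confidence=float(rng.random()),
        )
        for _ in range(n)
    ]


@pytest.mark.parametrize("seed", range(50))
def test_nms_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    boxes = _random_boxes(rng)
    lam = float(rng.uniform(0.1, 0.6))
    assert nms(boxes, lam) == _nms_oracle(boxes, lam)


def test_nms_singleton_and_duplicate():
    solo = ScoredBox(5, 5, 10, 10, 0.7)
    assert nms([solo], 0.5) == [solo]
    hi = ScoredBox(5, 5, 10, 10, 0.9)
    lo = ScoredBox(5, 5, 10, 10, 0.8)
    assert nms([lo, hi], 0.5) == [hi]


def test_nms_properties():
    rng = np.random.default_rng(7)
    boxes = _random_boxes(rng, 150)
    kept = nms(boxes, 0.3)
    # subset, non-increasing confidence, pairwise IOU <= lambda, idempotent
    assert set(id(b) for b in kept) <= set(id(b) for b in boxes)
    confs = [b.confidence for b in kept]
    assert confs == sorted(confs, reverse=True)
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            assert iou(kept[i], kept[j]) <= 0.3
    assert nms(kept, 0.3) == kept


def test_nms_input_order_invariance():
    rng = np.random.default_rng(8)
    boxes = _random_boxes(rng, 80)
    shuffled = [boxes[i] for i in rng.permutation(80)]
    a = nms(boxes, 0.4)
    b = nms(shuffled, 0.4)
    assert [(x.x, x.y, x.confidence) for x in a] == [(x.x, x.y, x.confidence) for x in b]


def test_box_at_exactly_lambda_survives():
    # IOU((0,0,2,2),(1,1,2,2)) = 1/7; boxes at exactly lambda are kept
    a = ScoredBox(0, 0, 2, 2, 0.9)
    b = ScoredBox(1, 1, 2, 2, 0.8)
    assert nms([a, b], 1 / 7) == [a, b]
    assert nms([a, b], 1 / 7 - 1e-9) == [a]


# ---------------------------------------------------------------------------
# window scoring


def test_window_patch_extraction_matches_per_crop_resize():
    from PIL import Image

    rng = np.random.default_rng(3)
    img = rng.integers(0, 255, size=(48, 40, 3), dtype=np.uint8)
    origins = [(0, 0), (8, 4), (17, 16)]
    batch = extract_window_patches(img, origins, (32, 22))
    for k, (x, y) in enumerate(origins):
        ref = Image.fromarray(img[y : y + 32, x : x + 22]).resize((32, 32), Image.BILINEAR)
        assert np.allclose(batch[k], np.asarray(ref, dtype=np.float32) / 255.0,
                           atol=2 / 255)


def test_scoring_requires_trained_model():
    from earcount.classifier import build_cnn_classifier

    model = build_cnn_classifier(0)  # never trained
    img = np.zeros((64, 64, 3), dtype=np.uint8)
    with pytest.raises(RuntimeError):
        score_windows(model, img, NmsConfig())


def test_blank_background_yields_no_detections(toy_classifier):
    model, _, _ = toy_classifier
    rng = np.random.default_rng(0)
    green = np.clip(rng.normal(0, 6, (64, 44, 3)) + (40, 150, 60), 0, 255).astype(np.uint8)
    boxes = score_windows(model, green, NmsConfig(window=(32, 32), stride=(4, 4)))
    assert boxes == []


def test_scoring_threshold_and_count_bound(toy_classifier):
    from conftest import paint_blob

    model, _, _ = toy_classifier
    rng = np.random.default_rng(1)
    img = np.clip(rng.normal(0, 6, (64, 44, 3)) + (40, 150, 60), 0, 255)
    paint_blob(img, 22, 32)
    img = img.astype(np.uint8)
    cfg = NmsConfig(window=(32, 32), stride=(4, 4), confidence_threshold=0.5)
    boxes = score_windows(model, img, cfg)
    n_windows = len(enumerate_windows((64, 44), (32, 32), (4, 4)))
    assert 0 < len(boxes) <= n_windows
    assert all(b.confidence >= 0.5 for b in boxes)
    # an impossible threshold keeps nothing
    cfg_hi = NmsConfig(window=(32, 32), stride=(4, 4), confidence_threshold=1.0)
    assert all(b.confidence >= 1.0 for b in score_windows(model, img, cfg_hi))
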
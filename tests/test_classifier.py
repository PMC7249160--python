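"""Classifier CNN: architecture conformance, training behaviour, baseline,
and confusion metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earcount.classifier import (
    HOG_DESCRIPTOR_LENGTH,
    ClassifierConfig,
    HogSvmClassifier,
    build_cnn_classifier,
    classification_metrics,
    hog_svm_classifier,
    predict_confidence,
    train_classifier,
)
from earcount.patches import KERNEL, NON_KERNEL, Patch, PatchDataset

# expected per-layer output shapes on a 32x32x3 input (conv/pool/FC rows)
CLASSIFIER_SHAPES = [
    (30, 30, 32),  # conv 3x3, 32 filters
    (28, 28, 32),  # conv 3x3, 32
    (14, 14, 32),  # avg pool 2x2 / s2
    (12, 12, 64),  # conv 3x3, 64
    (10, 10, 64),  # conv 3x3, 64
    (8, 8, 64),  # conv 3x3, 64
    (2, 2, 64),  # avg pool 7x7 / s1
    (256,),  # FC-256
    (128,),  # FC-128
    (1,),  # FC-1 -> sigmoid confidence
]


def test_architecture_shapes_match_specification():
    model = build_cnn_classifier(0)
    shapes = model.layer_shapes()
    # keep only shape-changing layers (convs, pools, flatten/dense)
    probe = []
    for s in shapes:
        if not probe or s != probe[-1]:
            probe.append(s)
    assert probe == [
        (30, 30, 32), (28, 28, 32), (14, 14, 32), (12, 12, 64),
        (10, 10, 64), (8, 8, 64), (2, 2, 64), (256,), (128,), (1,),
    ]


def test_forward_pass_shapes_on_real_tensor():
    model = build_cnn_classifier(0)
    x = np.random.default_rng(0).random((2, 32, 32, 3)).astype(np.float32)
    h = x
    seen = []
    for layer in model.layers:
        h = layer.forward(h)
        seen.append(h.shape[1:])
    for expected in CLASSIFIER_SHAPES:
        assert expected in seen
    assert h.shape == (2, 1)


def test_confidence_is_probability(toy_classifier):
    model, _, test = toy_classifier
    x, _ = test.as_arrays()
    conf = predict_confidence(model, x)
    assert np.all((conf >= 0) & (conf <= 1))


def test_batched_equals_single_patch_scoring(toy_classifier):
    model, _, test = toy_classifier
    x, _ = test.as_arrays()
    batched = predict_confidence(model, x[:6])
    singles = [predict_confidence(model, x[i]) for i in range(6)]
    assert np.allclose(batched, singles, atol=1e-5)
    assert predict_confidence(model, x[0]) == predict_confidence(model, x[0])


def test_training_separates_toy_classes(toy_classifier):
    model, history, test = toy_classifier
    assert history.train_loss[-1] < history.train_loss[0]
    x, y = test.as_arrays()
    pred = (predict_confidence(model, x) >= 0.5).astype(int)
    m = classification_metrics(y.astype(int), pred)
    assert m.accuracy == 1.0


def test_training_is_seed_deterministic(toy_split):
    train, test = toy_split
    config = ClassifierConfig(batch_size=16, total_iterations=12, eval_interval=4,
                              rng_seed=11)
    _, h1 = train_classifier(train, test, config)
    _, h2 = train_classifier(train, test, config)
    assert h1.train_loss == h2.train_loss
    assert h1.test_loss == h2.test_loss


def test_plateau_reduces_learning_rate(toy_split):
    train, test = toy_split
    config = ClassifierConfig(batch_size=16, total_iterations=40, eval_interval=2,
                              plateau_patience=2, plateau_min_delta=10.0,  # force stall
                              rng_seed=1)
    _, history = train_classifier(train, test, config)
    assert history.learning_rate[0] == config.lr_initial
    assert history.learning_rate[-1] == config.lr_reduced


def test_single_class_training_rejected():
    base = np.zeros((32, 32, 3), dtype=np.uint8)
    ds = PatchDataset([Patch(pixels=base, label=NON_KERNEL) for _ in range(10)])
    with pytest.raises(ValueError):
        train_classifier(ds, ds, ClassifierConfig(total_iterations=1))


def test_invalid_patch_shape_rejected(toy_classifier):
    model, _, _ = toy_classifier
    with pytest.raises(ValueError):
        predict_confidence(model, np.zeros((16, 16, 3), dtype=np.float32))


class TestHogSvm:
    def test_descriptor_length(self):
        # ((32/4 - 2) + 1)^2 blocks x 2x2 cells x 9 bins = 1764
        assert HOG_DESCRIPTOR_LENGTH == 1764
        patch = np.zeros((1, 32, 32, 3), dtype=np.float32)
        assert HogSvmClassifier.descriptors(patch).shape == (1, 1764)

    def test_constant_patch_has_zero_descriptor(self):
        gray = np.full((1, 32, 32, 3), 0.5, dtype=np.float32)
        desc = HogSvmClassifier.descriptors(gray)
        assert np.allclose(desc, 0.0, atol=1e-7)

    def test_separable_fixture_perfect_accuracy(self, toy_split):
        train, test = toy_split
        baseline = hog_svm_classifier(train)
        x, y = test.as_arrays()
        pred = (baseline.predict_confidence(x) >= 0.5).astype(int)
        assert classification_metrics(y.astype(int), pred).accuracy == 1.0

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            HogSvmClassifier().predict_confidence(np.zeros((1, 32, 32, 3), np.float32))


class TestMetrics:
    def test_reported_confusion_arithmetic(self):
        """Accuracy from printed FP/FN counts on a 3278-patch test set."""
        n, n_pos = 3278, 1396
        for fp, fn, acc, f in [(19, 22, 0.987, 0.985), (135, 135, 0.918, 0.903)]:
            labels = np.array([1] * n_pos + [0] * (n - n_pos))
            preds = labels.copy()
            preds[:fn] = 0  # kernels missed
            preds[n_pos : n_pos + fp] = 1  # non-kernels flagged
            m = classification_metrics(labels, preds)
            assert m.fp == fp and m.fn == fn
            assert round(m.accuracy, 3) == acc
            assert round(m.f_score, 3) == f

    def test_perfect_prediction(self):
        labels = np.array([1, 0, 1, 1, 0])
        m = classification_metrics(labels, labels)
        assert (m.fp, m.fn, m.accuracy, m.f_score) == (0, 0, 1.0, 1.0)

    @pytest.mark.filterwarnings("ignore:no positive labels")
    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=60))
    def test_accuracy_identity(self, pairs):
        labels = [a for a, _ in pairs]
        preds = [b for _, b in pairs]
        m = classification_metrics(labels, preds)
        assert m.accuracy == pytest.approx(1 - (m.fp + m.fn) / m.n)
        assert 0 <= m.f_score <= 1

    def test_no_positives_anywhere_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            m = classification_metrics([0, 0], [0, 0])
        assert m.f_score == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([0, 1], [1])
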
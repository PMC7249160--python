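"""Desk-scale end-to-end evaluation of the counting pipeline.

Since no annotated ear-image corpus is public, the pipeline is judged by a
parameter-recovery experiment on synthetic scenes: train both CNNs on
patches cut from seeded training scenes, run the full pipeline on held-out
scenes, and score detection recall, false-positive rate, center-regression
error, and whole-ear count accuracy (RMSE / MAE / Pearson correlation)
against the generator's exact ground truth.

Scene scale for this experiment: single ears of roughly 200-350 visible
kernels rendered at a kernel size matched to the 32x22 detection window
(as in the source imagery the defaults emulate), in ~900x450 px frames —
sized so the whole experiment runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .classifier import ClassifierConfig, classification_metrics, predict_confidence, train_classifier
from .counting import CountingConfig, count_kernels, count_metrics
from .patches import PatchDataset, augment_patches, extract_negative_patches, extract_positive_patches, split_dataset
from .regressor import RegressorConfig, train_regressor
from .synthetic import EarSceneParams, render_ear_image

__all__ = [
    "RecoveryConfig",
    "recovery_scene_params",
    "build_patch_corpus",
    "match_centers",
    "run_recovery_experiment",
]


def recovery_scene_params(seed: int, **overrides) -> EarSceneParams:
    """Evaluation-scale single-ear scene parameters.

    Same lattice statistics as the full-size defaults (200-300 visible
    kernels, staggered near-touching columns, varied tilt and lighting)
    but rendered at a 2x smaller kernel size with tight framing, with the
    detection window scaled alongside (see ``recovery_nms_config``), so
    the ten-scene experiment runs in minutes on one CPU.
    """
    defaults = dict(
        image_size=(480, 224),
        n_ears=1,
        kernels_per_column=(17, 21),
        visible_columns=(12, 14),
        kernel_radius=(5.0, 6.0),
        ear_tilt=(-8.0, 8.0),
        lighting_gain=(0.8, 1.15),
        jitter=0.4,
        rng_seed=seed,
    )
    defaults.update(overrides)
    return EarSceneParams(**defaults)


def recovery_nms_config(**overrides) -> "NmsConfig":
    """Detection config with the window scaled to the evaluation kernels.

    As in the source design — where the 32x22 window matches one kernel
    row pitch of the ~30 px kernels — the window height equals the row
    pitch (3r = 15-18 px here), giving 15x10 at the same aspect ratio.
    At this window:pitch geometry, boxes kept on adjacent kernels overlap
    by at most ~0.21 IOU while duplicate boxes on one kernel overlap by
    0.25 or more, so the NMS overlap threshold is set between the two
    (0.25); the sensitivity of counts to this threshold is inherent to
    the method.
    """
    from .detection import NmsConfig

    defaults = dict(window=(15, 10), overlap_threshold=0.25)
    defaults.update(overrides)
    return NmsConfig(**defaults)


@dataclass(frozen=True)
class RecoveryConfig:
    n_train_scenes: int = 10
    n_eval_scenes: int = 10
    n_negatives_per_scene: int = 250
    augment_fraction: float = 0.7
    test_fraction: float = 0.2
    classifier_iterations: int = 150
    regressor_iterations: int = 600
    counting: CountingConfig | None = None


def build_patch_corpus(scene_seeds, n_negatives_per_scene: int = 200,
                       window: tuple[int, int] = (15, 10),
                       stride: tuple[int, int] = (4, 4),
                       scene_params=recovery_scene_params):
    """Positive and negative patches pooled over seeded scenes.

    Positives are window-sized crops snapped to the detection stride grid
    (the distribution the classifier sees at scan time); the single-kernel
    labeling rule still decides which kernels qualify.  Negatives are
    random crops with zero or several kernels at matching scale.
    """
    positives, negatives = [], []
    for s in scene_seeds:
        scene = render_ear_image(scene_params(s))
        positives.extend(extract_positive_patches(
            scene, crop_size=window, align_stride=stride, source=f"scene{s}"))
        negatives.extend(extract_negative_patches(
            scene, n_negatives_per_scene, rng_seed=s + 1, crop_size=window,
            source=f"scene{s}"))
    return PatchDataset(positives), PatchDataset(negatives)


def match_centers(detected: np.ndarray, truth: np.ndarray, tolerance: float):
    """One-to-one assignment of detections to ground-truth centers.

    Pairs further apart than ``tolerance`` never match.  Returns
    (n_matched, n_detected, n_truth).
    """
    detected = np.asarray(detected).reshape(-1, 2)
    truth = np.asarray(truth).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        return 0, len(detected), len(truth)
    d = np.linalg.norm(detected[:, None, :] - truth[None, :, :], axis=2)
    cost = np.where(d <= tolerance, d, 1e9)
    rows, cols = linear_sum_assignment(cost)
    matched = int((d[rows, cols] <= tolerance).sum())
    return matched, len(detected), len(truth)


def run_recovery_experiment(seed: int, config: RecoveryConfig = RecoveryConfig(),
                            verbose: bool = False) -> dict:
    """Train on synthetic patches, count held-out scenes, return metrics."""
    rng = np.random.default_rng(seed)
    base = int(rng.integers(1, 2**20))
    train_seeds = [base + i for i in range(config.n_train_scenes)]
    eval_seeds = [base + 10_000 + i for i in range(config.n_eval_scenes)]

    counting = config.counting or CountingConfig(nms=recovery_nms_config())
    positives, negatives = build_patch_corpus(
        train_seeds, n_negatives_per_scene=config.n_negatives_per_scene,
        window=counting.nms.window, stride=counting.nms.stride)
    corpus = positives.extend(negatives)
    train_set, test_set = split_dataset(corpus, config.test_fraction, rng_seed=seed + 1)
    train_set = PatchDataset(
        augment_patches(train_set.patches, config.augment_fraction, rng_seed=seed + 2),
        rng_seed=seed + 2)

    cls_cfg = ClassifierConfig(total_iterations=config.classifier_iterations,
                               rng_seed=seed + 3)
    classifier, cls_history = train_classifier(train_set, test_set, cls_cfg)
    x_test, y_test = test_set.as_arrays()
    cls_pred = (predict_confidence(classifier, x_test) >= 0.5).astype(int)
    cls_metrics = classification_metrics(y_test.astype(int), cls_pred)

    pos_train, pos_test = split_dataset(positives, config.test_fraction, rng_seed=seed + 4)
    # The narrow FC-10 bottleneck occasionally yields an initialisation
    # whose training stalls on one output coordinate (final training loss
    # stays in pixels instead of dropping well below one); restart from a
    # reseeded init when that happens.  Decided on training loss only.
    regressor = reg_history = None
    for attempt in range(3):
        reg_cfg = RegressorConfig(total_iterations=config.regressor_iterations,
                                  rng_seed=seed + 5 + 1000 * attempt)
        regressor, reg_history = train_regressor(pos_train, pos_test, reg_cfg)
        if reg_history.train_loss[-1] < 1.0:
            break
    from .regressor import predict_center  # local import avoids cycle at top
    xp, _, tp = pos_test.as_arrays(with_centers=True)
    pred_centers = predict_center(regressor, xp)
    center_err = float(np.linalg.norm(pred_centers - tp, axis=1).mean())
    n_center_test = len(xp)

    scenes = []
    for s in eval_seeds:
        scene = render_ear_image(recovery_scene_params(s))
        estimate = count_kernels(scene, classifier, regressor, counting)
        tol = scene.ears[0].radius  # one kernel half-width
        matched, n_det, n_truth = match_centers(estimate.centers, scene.centers, tol)
        truth_total = scene.total_kernels
        scenes.append({
            "seed": s,
            "n_visible_truth": n_truth,
            "n_detected": estimate.n_detected,
            "matched": matched,
            "recall": matched / n_truth if n_truth else float("nan"),
            "fp_rate": (n_det - matched) / n_det if n_det else 0.0,
            "total_truth": truth_total,
            "total_predicted": estimate.total,
            "rel_count_error": (estimate.total - truth_total) / truth_total,
        })
        if verbose:
            print(f"scene {s}: visible {n_truth}, detected {n_det}, "
                  f"matched {matched}, total {estimate.total}/{truth_total}")

    predicted = [sc["total_predicted"] for sc in scenes]
    actual = [sc["total_truth"] for sc in scenes]
    cmetrics = count_metrics(predicted, actual)
    recalls = np.array([sc["recall"] for sc in scenes])
    fp_rates = np.array([sc["fp_rate"] for sc in scenes])
    within_15 = int(sum(abs(sc["rel_count_error"]) <= 0.15 for sc in scenes))

    return {
        "scenes": scenes,
        "n_patches": len(corpus),
        "classifier_metrics": cls_metrics,
        "classifier_history": cls_history,
        "regressor_history": reg_history,
        "center_error_px": center_err,
        "n_center_test_patches": n_center_test,
        "mean_recall": float(recalls.mean()),
        "min_recall": float(recalls.min()),
        "mean_fp_rate": float(fp_rates.mean()),
        "max_fp_rate": float(fp_rates.max()),
        "scenes_within_15pct": within_15,
        "count_rmse": cmetrics.rmse,
        "count_mae": cmetrics.mae,
        "count_correlation": cmetrics.correlation,
        "models": (classifier, regressor),
    }
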
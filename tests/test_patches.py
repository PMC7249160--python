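"""Patch extraction, labeling rules, augmentation, and splitting."""

import numpy as np
import pytest

from earcount.patches import (
    KERNEL,
    NON_KERNEL,
    Patch,
    PatchDataset,
    augment_patches,
    extract_negative_patches,
    extract_positive_patches,
    split_dataset,
)
from earcount.synthetic import AnnotatedImage, EarSceneParams, render_ear_image


def _sparse_image(centers, box_size=12.0, size=(200, 200)):
    """Gray image with declared kernel centers and tight boxes."""
    rng = np.random.default_rng(0)
    pixels = rng.integers(60, 200, size=(*size, 3), dtype=np.uint8)
    centers = np.asarray(centers, dtype=float)
    boxes = np.column_stack([
        centers[:, 0] - box_size / 2, centers[:, 1] - box_size / 2,
        np.full(len(centers), box_size), np.full(len(centers), box_size),
    ])
    return AnnotatedImage(pixels=pixels, centers=centers, boxes=boxes)


class TestPositiveExtraction:
    def test_well_separated_kernels_all_extracted(self):
        image = _sparse_image([(30, 30), (100, 50), (60, 150), (160, 160)])
        patches = extract_positive_patches(image, margin=2)
        assert len(patches) == 4
        assert all(p.label == KERNEL for p in patches)

    def test_two_close_kernels_both_skipped(self):
        """A crop that would show two kernels is not a positive sample."""
        image = _sparse_image([(100, 100), (102, 100)], box_size=20)
        assert extract_positive_patches(image, margin=0) == []

    def test_center_round_trip_within_half_pixel(self):
        scene = render_ear_image(EarSceneParams(
            image_size=(400, 200), visible_columns=(10, 12),
            kernels_per_column=(12, 14), kernel_radius=(5, 6), rng_seed=8))
        patches = extract_positive_patches(scene, margin=1)
        assert len(patches) >= 100
        for p in patches[:200]:
            # map the stored patch center back through the crop transform
            x0, y0 = p.origin
            cw, ch = p.crop_size
            back = (x0 + p.center[0] * cw / 32, y0 + p.center[1] * ch / 32)
            # it must coincide with exactly one ground-truth center
            dist = np.linalg.norm(scene.centers - back, axis=1)
            assert dist.min() <= 0.5


class TestNegativeExtraction:
    def test_blank_image_returns_requested_count(self):
        image = AnnotatedImage(
            pixels=np.full((100, 100, 3), 90, dtype=np.uint8),
            centers=np.empty((0, 2)))
        patches = extract_negative_patches(image, 25, rng_seed=1)
        assert len(patches) == 25
        assert all(p.label == NON_KERNEL for p in patches)

    def test_two_kernel_crop_is_negative(self):
        """A crop containing two kernel centers qualifies as a negative."""
        image = _sparse_image([(50, 50), (58, 50)], box_size=10, size=(70, 108))
        patches = extract_negative_patches(image, 40, rng_seed=2, crop_size=(30, 30))
        for p in patches:
            x0, y0 = p.origin
            n_inside = sum(
                x0 <= cx < x0 + 30 and y0 <= cy < y0 + 30
                for cx, cy in image.centers)
            assert n_inside != 1

    def test_seeded_determinism(self):
        image = _sparse_image([(60, 60)], size=(120, 120))
        a = extract_negative_patches(image, 10, rng_seed=5)
        b = extract_negative_patches(image, 10, rng_seed=5)
        assert [p.origin for p in a] == [p.origin for p in b]
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))


class TestAugmentation:
    def _dummies(self, n, with_center=False):
        base = np.full((32, 32, 3), 120, dtype=np.uint8)
        center = (4.0, 16.0) if with_center else None
        label = KERNEL if with_center else NON_KERNEL
        return [Patch(pixels=base, label=label, center=center) for _ in range(n)]

    def test_seventy_percent_augmentation_count(self):
        out = augment_patches(self._dummies(13113), fraction=0.7, rng_seed=0)
        assert len(out) == 22292  # 13113 + round(0.7 * 13113)

    def test_zero_fraction_is_identity(self):
        patches = self._dummies(10)
        assert augment_patches(patches, fraction=0.0, rng_seed=0) == patches

    def test_flip_mirrors_center_and_pixels_consistently(self):
        """x -> 32 - x under a left-right flip, verified on a marker pixel."""
        pixels = np.zeros((32, 32, 3), dtype=np.uint8)
        pixels[16, 4] = 255  # pixel column 4 covers x in [4, 5)
        patch = Patch(pixels=pixels, label=KERNEL, center=(4.5, 16.5))
        found_h = False
        for seed in range(40):
            (out,) = augment_patches([patch], fraction=1.0, rng_seed=seed)[1:]
            marker_cols = np.flatnonzero(out.pixels.sum(axis=(0, 2)))
            marker_rows = np.flatnonzero(out.pixels.sum(axis=(1, 2)))
            if marker_cols[0] == 27:  # horizontally flipped
                found_h = True
                assert out.center[0] == pytest.approx(32 - 4.5)
                assert marker_rows[0] in (16, 15)
        assert found_h

    def test_labels_never_change(self):
        patches = self._dummies(20) + self._dummies(20, with_center=True)
        out = augment_patches(patches, fraction=1.0, rng_seed=3)
        assert sum(p.label == KERNEL for p in out) == 40
        assert all((p.center is not None) == (p.label == KERNEL) for p in out)


class TestSplit:
    def _dataset(self, n):
        base = np.zeros((32, 32, 3), dtype=np.uint8)
        return PatchDataset([Patch(pixels=base, label=NON_KERNEL) for _ in range(n)])

    @pytest.mark.parametrize("n,frac,expected_test", [
        (16391, 0.2, 3278),  # 3278.2 rounds to 3278
        (6978, 0.2, 1396),  # 1395.6 rounds to 1396
    ])
    def test_round_to_nearest_sizes(self, n, frac, expected_test):
        train, test = split_dataset(self._dataset(n), frac, rng_seed=0)
        assert len(test) == expected_test
        assert len(train) == n - expected_test

    def test_partition_property(self):
        ds = self._dataset(101)
        for p in ds.patches:
            p.source = str(id(p))
        train, test = split_dataset(ds, 0.3, rng_seed=5)
        assert len(train) + len(test) == 101
        assert {id(p) for p in train.patches}.isdisjoint({id(p) for p in test.patches})

    def test_seed_reproduces_membership(self):
        ds = self._dataset(50)
        a = split_dataset(ds, 0.2, rng_seed=9)
        b = split_dataset(ds, 0.2, rng_seed=9)
        assert [id(p) for p in a[1].patches] == [id(p) for p in b[1].patches]

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._dataset(3), 0.01, rng_seed=0)


def test_patch_validation():
    base = np.zeros((32, 32, 3), dtype=np.uint8)
    with pytest.raises(ValueError):
        Patch(pixels=np.zeros((16, 16, 3), dtype=np.uint8), label=KERNEL)
    with pytest.raises(ValueError):
        Patch(pixels=base, label=NON_KERNEL, center=(4, 4))
    with pytest.raises(ValueError):
        Patch(pixels=base, label=KERNEL, center=(33.0, 4.0))
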
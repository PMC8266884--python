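"""Geometric augmentation and slice-level class balancing."""

import numpy as np
import pytest

from deepmir.augment import (
    AugmentationPolicy,
    BalancingError,
    augment_slice,
    balance_and_augment,
    mirror_slice,
    rotate_slice,
    translate_slice,
)
from deepmir.io_types import CLASS_CMB, CLASS_IRON, ValidationError
from deepmir.preprocess import SliceSample


def make_sample(size=64, lesions=(), rng=None, pid="p", idx=0):
    rng = rng or np.random.default_rng(0)
    image = rng.normal(size=(1, size, size)).astype(np.float32)
    label = np.zeros((size, size), dtype=np.int16)
    for (r, c, cls) in lesions:
        label[r, c] = cls
    return SliceSample(
        image=image, label=label, participant_id=pid, slice_index=idx,
        has_lesion={CLASS_CMB: bool((label == 1).any()),
                    CLASS_IRON: bool((label == 2).any())},
        orig_shape=(size, size),
    )


class TestTranslate:
    def test_zero_shift_is_identity(self):
        s = make_sample(lesions=[(30, 30, 1)])
        out = translate_slice(s, 0, 0)
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.label, s.label)

    def test_single_voxel_moves_by_shift(self):
        s = make_sample(lesions=[(30, 30, 1)])
        out = translate_slice(s, 10, -5)
        assert np.argwhere(out.label == 1).tolist() == [[40, 25]]
        assert out.label.sum() == 1  # count preserved away from borders

    def test_lesion_leaving_field_disappears(self):
        s = make_sample(size=64, lesions=[(60, 60, 1)])
        out = translate_slice(s, 10, 10)
        assert not out.label.any()
        assert not out.has_lesion[CLASS_CMB]

    def test_out_of_range_shift_rejected(self):
        s = make_sample()
        with pytest.raises(ValidationError):
            translate_slice(s, 46, 0)


class TestRotate:
    def test_inverse_pair_near_identity(self):
        s = make_sample()
        # smooth image: linear interpolation can round-trip it
        yy, xx = np.mgrid[0:64, 0:64] / 64.0
        s.image[0] = np.sin(2 * np.pi * yy) + np.cos(2 * np.pi * xx)
        plus, _ = rotate_slice(s, 30)
        _, back = rotate_slice(plus, 30)
        inner = slice(16, 48)  # away from corners lost to edge fill
        err = np.abs(back.image[0, inner, inner] - s.image[0, inner, inner])
        assert np.median(err) < 0.05  # interpolation tolerance

    def test_center_voxel_is_fixed_point(self):
        # odd-sized slice so the rotation center is a grid point
        s = make_sample(size=65, lesions=[(32, 32, 1)])
        for d in (1, 17, 60):
            plus, minus = rotate_slice(s, d)
            assert plus.label[32, 32] == 1
            assert minus.label[32, 32] == 1

    def test_offcenter_voxel_follows_rotation_matrix(self):
        s = make_sample(size=65, lesions=[(20, 32, 1)])
        d = 60
        plus, _ = rotate_slice(s, d)
        got = np.argwhere(plus.label == 1)
        assert len(got) == 1
        th = np.deg2rad(d)
        disp = np.array([20 - 32, 32 - 32], dtype=float)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        expected = rot @ disp + 32
        assert np.linalg.norm(got[0] - expected) <= 1.0  # nearest grid point

    def test_angle_out_of_range_rejected(self):
        s = make_sample()
        for d in (0, 61, 90):
            with pytest.raises(ValidationError):
                rotate_slice(s, d)


class TestMirror:
    def test_involution(self):
        s = make_sample(lesions=[(10, 20, 2)])
        out = mirror_slice(mirror_slice(s))
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.label, s.label)

    def test_column_mapping(self):
        s = make_sample(size=64, lesions=[(10, 20, 1)])
        out = mirror_slice(s)
        assert np.argwhere(out.label == 1).tolist() == [[10, 63 - 20]]

    def test_symmetric_image_unchanged(self):
        s = make_sample()
        s.image[0] = s.image[0] + s.image[0, :, ::-1]  # make it LR symmetric
        assert np.allclose(mirror_slice(s).image, s.image)


class TestAugmentationPolicy:
    def test_multiclass_yield_exceeds_single_class(self):
        policy = AugmentationPolicy()
        assert policy.yield_per_slice("multiclass") > policy.yield_per_slice(
            "single_class_cmb")

    def test_default_counts(self):
        policy = AugmentationPolicy()
        assert policy.counts_for("multiclass") == (10, 16)
        assert policy.counts_for("single_class_cmb") == (5, 8)
        assert policy.translation_range == (-45, 45)
        assert policy.rotation_range == (1, 60)

    def test_labels_only_contain_source_classes(self, rng):
        s = make_sample(lesions=[(30, 30, 1), (40, 40, 1)])
        policy = AugmentationPolicy(n_translations=3, n_rotations=3)
        for out in augment_slice(s, policy, "multiclass", rng):
            assert set(np.unique(out.label)).issubset({0, 1})


class TestBalanceAndAugment:
    def _samples(self, n_lesion=3, n_empty=20):
        rng = np.random.default_rng(5)
        out = [make_sample(lesions=[(30 + i, 30, 1)], rng=rng, idx=i)
               for i in range(n_lesion)]
        out += [make_sample(rng=rng, idx=100 + i) for i in range(n_empty)]
        return out

    def test_groups_balanced_within_one_yield(self):
        policy = AugmentationPolicy(seed=3, translation_range=(-8, 8))
        out = balance_and_augment(self._samples(), policy, "multiclass")
        bearing = sum(1 for s in out if s.has_lesion[CLASS_CMB])
        empty = len(out) - bearing
        assert abs(bearing - empty) < policy.yield_per_slice("multiclass")

    def test_trivial_policy_is_identity(self):
        samples = self._samples(n_lesion=2, n_empty=2)
        policy = AugmentationPolicy(n_translations=0, n_rotations=0,
                                    mirror_lr=False,
                                    single_class_n_translations=0,
                                    single_class_n_rotations=0)
        out = balance_and_augment(samples, policy, "single_class_cmb")
        # every lesion slice once, plus empty slices up to balance
        assert len(out) == 4
        assert sum(1 for s in out if s.has_lesion[CLASS_CMB]) == 2

    def test_seeded_determinism(self):
        policy = AugmentationPolicy(seed=11, translation_range=(-8, 8),
                                    n_translations=2, n_rotations=2)
        a = balance_and_augment(self._samples(), policy, "multiclass")
        b = balance_and_augment(self._samples(), policy, "multiclass")
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)
            assert np.array_equal(x.label, y.label)

    def test_no_lesion_slices_rejected(self):
        with pytest.raises(BalancingError):
            balance_and_augment(self._samples(n_lesion=0), AugmentationPolicy(),
                                "single_class_cmb")

    def test_single_class_task_ignores_other_class(self):
        rng = np.random.default_rng(8)
        samples = [make_sample(lesions=[(30, 30, 2)], rng=rng)]  # iron only
        with pytest.raises(BalancingError):
            balance_and_augment(samples, AugmentationPolicy(), "single_class_cmb")
        out = balance_and_augment(samples, AugmentationPolicy(
            single_class_n_translations=1, single_class_n_rotations=1,
            translation_range=(-8, 8)), "single_class_iron")
        assert len(out) > 0
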
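"""Lesion extraction, centroid matching, detection metrics and statistics."""

import itertools
import math

import numpy as np
import pytest

from deepmir.evaluation import (
    DetectionCounts,
    LesionSet,
    accuracy,
    binarize,
    bland_altman,
    compare_models,
    correlate_counts,
    evaluate_cohort,
    extract_lesions,
    magnitude_accuracy,
    match_lesions,
    precision,
    sensitivity,
)
from deepmir.io_types import CLASS_CMB, CLASS_IRON, ExperimentConfig, ValidationError


# ---------------------------------------------------------------------------
# independent oracles


def flood_fill_components(mask, connectivity):
    """Brute-force connected components by breadth-first flood fill."""
    mask = np.asarray(mask).astype(bool)
    if connectivity == 6:
        neigh = [d for d in itertools.product((-1, 0, 1), repeat=3)
                 if sum(map(abs, d)) == 1]
    else:
        neigh = [d for d in itertools.product((-1, 0, 1), repeat=3)
                 if any(d)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = []
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in neigh:
                w = tuple(a + b for a, b in zip(v, d))
                if all(0 <= c < s for c, s in zip(w, mask.shape)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


def exact_wilcoxon_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # handle ties by average ranks
    absd = np.abs(d)
    for v in np.unique(absd):
        idx = absd == v
        ranks[idx] = ranks[idx].mean()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    total = 2**n
    for signs in itertools.product((0, 1), repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_plus, ranks.sum() - w_plus)
        if w <= w_obs:
            count += 1
    return count / total


# ---------------------------------------------------------------------------


class TestBinarize:
    def test_threshold_is_inclusive_at_half(self):
        p = np.array([[[0.49, 0.51]]])
        out = binarize(p, "single_class_cmb", 0.5)
        assert out.tolist() == [[[0, 1]]]

    def test_multiclass_argmax(self):
        p = np.array([0.2, 0.3, 0.5]).reshape(3, 1, 1, 1)
        assert binarize(p, "multiclass")[0, 0, 0] == 2

    def test_uniform_tie_goes_to_lowest_class(self):
        p = np.full((3, 1, 1, 1), 1 / 3)
        assert binarize(p, "multiclass")[0, 0, 0] == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            binarize(np.array([1.2]), "single_class_cmb")


class TestExtractLesions:
    def test_two_separate_clusters(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[2, 2, 2] = True
        mask[12, 2, 2] = True
        assert len(extract_lesions(mask)) == 2

    def test_volume_arithmetic(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[1, 1, 1:5] = True  # 4 voxels
        les = extract_lesions(mask, voxel_dims=(1.0, 1.0, 1.5))
        assert les.lesions[0].volume_mm3 == pytest.approx(6.0)

    def test_diagonal_adjacency_by_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True  # corner neighbours
        assert len(extract_lesions(mask, connectivity=26)) == 1
        assert len(extract_lesions(mask, connectivity=6)) == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity, rng):
        # exhaustive over all 2^8 2x2x2 masks
        for bits in range(256):
            mask = np.array([(bits >> i) & 1 for i in range(8)]).reshape(2, 2, 2)
            ours = extract_lesions(mask, connectivity=connectivity)
            oracle = flood_fill_components(mask, connectivity)
            got = {frozenset(map(tuple, l.voxels)) for l in ours.lesions}
            assert got == oracle
        # random 3^3 and 4^3 masks
        for shape, n in (((3, 3, 3), 100), ((4, 4, 4), 100)):
            for _ in range(n):
                mask = rng.random(shape) < 0.4
                ours = extract_lesions(mask, connectivity=connectivity)
                oracle = flood_fill_components(mask, connectivity)
                got = {frozenset(map(tuple, l.voxels)) for l in ours.lesions}
                assert got == oracle

    def test_centroid_is_unweighted_mean(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        les = extract_lesions(mask)
        assert les.lesions[0].centroid == (1.0, 1.0, 1.5)


def _set(centroids):
    from deepmir.evaluation import Lesion
    return LesionSet(lesions=[
        Lesion(id=i, voxels=np.array([c]), centroid=tuple(c), volume_mm3=1.5)
        for i, c in enumerate(centroids)])


class TestMatchLesions:
    def test_within_tolerance_is_tp(self):
        counts, pairs = match_lesions(_set([(11, 10, 10)]), _set([(10, 10, 10)]), 3)
        assert (counts.TP, counts.FP, counts.FN) == (1, 0, 0)
        assert pairs[0][2] == pytest.approx(1.0)

    def test_beyond_tolerance_is_fp_and_fn(self):
        counts, _ = match_lesions(_set([(20, 10, 10)]), _set([(10, 10, 10)]), 3)
        assert (counts.TP, counts.FP, counts.FN) == (0, 1, 1)

    def test_empty_prediction_all_fn(self):
        counts, _ = match_lesions(_set([]), _set([(1, 1, 1), (5, 5, 5)]), 3)
        assert (counts.TP, counts.FP, counts.FN) == (0, 0, 2)

    def test_tolerance_is_strict(self):
        counts, _ = match_lesions(_set([(13, 10, 10)]), _set([(10, 10, 10)]), 3)
        assert counts.TP == 0  # distance exactly 3 is not below tolerance

    def test_one_to_one_matching(self):
        # two predictions near one reference: only one TP
        counts, _ = match_lesions(_set([(10, 10, 10), (10, 10, 11)]),
                                  _set([(10, 10, 10)]), 3)
        assert (counts.TP, counts.FP, counts.FN) == (1, 1, 0)

    def test_greedy_prefers_closest_pair(self):
        pred = _set([(0, 0, 0), (0, 0, 2)])
        ref = _set([(0, 0, 1)])
        _, pairs = match_lesions(pred, ref, 3)
        assert pairs[0][0] == 0  # distance 1 beats distance 1... both 1: lowest
        counts, pairs = match_lesions(_set([(0, 0, 1.5), (0, 0, 0.9)]),
                                      _set([(0, 0, 1)]), 3)
        assert pairs[0][0] == 1  # the strictly closer prediction wins

    def test_tp_symmetric_under_swap(self, rng):
        a = _set(rng.uniform(0, 10, size=(5, 3)))
        b = _set(rng.uniform(0, 10, size=(7, 3)))
        ca, _ = match_lesions(a, b, 4)
        cb, _ = match_lesions(b, a, 4)
        assert ca.TP == cb.TP
        assert ca.FP == cb.FN and ca.FN == cb.FP

    def test_counts_account_for_all_lesions(self, rng):
        a = _set(rng.uniform(0, 8, size=(6, 3)))
        b = _set(rng.uniform(0, 8, size=(4, 3)))
        c, _ = match_lesions(a, b, 3)
        assert c.TP + c.FP == len(a)
        assert c.TP + c.FN == len(b)


class TestRatioMetrics:
    def test_missing_one_of_two_halves_sensitivity(self):
        assert sensitivity(DetectionCounts(TP=1, FN=1)) == 0.5

    def test_one_false_positive_halves_precision(self):
        assert precision(DetectionCounts(TP=1, FP=1)) == 0.5

    def test_perfect_detection(self):
        assert sensitivity(DetectionCounts(TP=2, FN=0)) == 1.0

    def test_undefined_ratios_are_nan_not_zero(self):
        assert math.isnan(sensitivity(DetectionCounts()))
        assert math.isnan(precision(DetectionCounts()))

    def test_magnitude_accuracy_values(self):
        assert magnitude_accuracy(1, 1) == pytest.approx(math.sqrt(2))
        assert magnitude_accuracy(0.6, 0.8) == pytest.approx(1.0)
        assert magnitude_accuracy(0, 0) == 0.0

    def test_voxel_accuracy_needs_tn(self):
        with pytest.raises(ValidationError):
            accuracy(DetectionCounts(TP=1, FP=1, FN=1))
        assert accuracy(DetectionCounts(TP=3, FP=1, FN=1, TN=5)) == 0.8


class TestStatistics:
    def test_pearson_perfect_correlations(self):
        x = [1.0, 2, 3, 5, 8]
        assert correlate_counts(x, x)[0] == pytest.approx(1.0)
        y = [-v + 3 for v in x]
        assert correlate_counts(x, y)[0] == pytest.approx(-1.0)

    def test_pearson_matches_hand_computation(self):
        x = np.array([2.0, 4, 5, 7, 9])
        y = np.array([1.0, 3, 2, 8, 7])
        r, _ = correlate_counts(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(expected, abs=1e-10)

    def test_pearson_undefined_for_constant_vector(self):
        r, p = correlate_counts([1.0, 1, 1, 1], [1.0, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p)

    def test_bland_altman_identical_vectors(self):
        assert bland_altman([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 0.0)

    def test_bland_altman_constant_offset(self):
        md, lo, hi = bland_altman([3, 4, 5], [1, 2, 3])
        assert (md, lo, hi) == (2.0, 2.0, 2.0)

    def test_bland_altman_hand_computed_fixture(self):
        pred = np.array([0.0, 1, 2, 5])
        ref = np.array([1.0, 1, 1, 1])  # differences: -1, 0, 1, 4
        md, lo, hi = bland_altman(pred, ref)
        sd = math.sqrt(((-2) ** 2 + (-1) ** 2 + 0**2 + 3**2) / 3)
        assert md == pytest.approx(1.0)
        assert lo == pytest.approx(1 - 1.96 * sd)
        assert hi == pytest.approx(1 + 1.96 * sd)

    def test_wilcoxon_shift_is_significant(self, rng):
        a = rng.normal(size=10)
        b = a + 5.0
        _, p = compare_models(a, b)
        assert p < 0.05

    def test_wilcoxon_identical_vectors_undefined(self):
        w, p = compare_models([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        assert math.isnan(w) and math.isnan(p)

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_wilcoxon_p_matches_exact_enumeration(self, n, rng):
        for trial in range(3):
            a = rng.normal(size=n)
            b = a + rng.normal(scale=1.0, size=n)
            _, p = compare_models(a, b)
            assert p == pytest.approx(exact_wilcoxon_p(a - b), abs=1e-10)


class TestEvaluateCohort:
    def _cfg(self):
        return ExperimentConfig(task="multiclass", modalities=("swi", "qsm"))

    def _volume_with(self, centroids, cls):
        grid = np.zeros((24, 24, 24), dtype=np.int16)
        for c in centroids:
            grid[c] = cls
        return grid

    def test_perfect_predictions(self):
        refs = {f"p{i}": self._volume_with([(2 + i, 3, 4), (10, 10 + i, 10)],
                                           CLASS_CMB) for i in range(3)}
        report = evaluate_cohort(refs, refs, self._cfg())
        avg = report.averages[CLASS_CMB]
        assert avg["sensitivity"] == 1.0 and avg["precision"] == 1.0
        assert report.magnitude_accuracy[CLASS_CMB]["norm_of_means"] == \
            pytest.approx(math.sqrt(2))

    def test_hand_computed_average_sensitivity(self):
        """One of four participants misses one of two lesions: S_bar = 0.875."""
        refs, preds = {}, {}
        for i in range(4):
            refs[f"p{i}"] = self._volume_with([(2, 2, 2), (15, 15, 15)], CLASS_CMB)
            if i == 0:
                preds[f"p{i}"] = self._volume_with([(2, 2, 2)], CLASS_CMB)
            else:
                preds[f"p{i}"] = refs[f"p{i}"].copy()
        report = evaluate_cohort(preds, refs, self._cfg())
        assert report.averages[CLASS_CMB]["sensitivity"] == pytest.approx(0.875)

    def test_empty_predictions(self):
        refs = {f"p{i}": self._volume_with([(3, 3, 3)], CLASS_CMB)
                for i in range(3)}
        preds = {f"p{i}": np.zeros((24, 24, 24), dtype=np.int16)
                 for i in range(3)}
        report = evaluate_cohort(preds, refs, self._cfg())
        avg = report.averages[CLASS_CMB]
        assert avg["sensitivity"] == 0.0
        assert math.isnan(avg["precision"])
        assert avg["n_excluded_precision"] == 3

    def test_iron_burden_uses_volume(self):
        refs = {}
        preds = {}
        rng = np.random.default_rng(0)
        for i in range(4):
            n = 2 + i
            cells = [(int(rng.integers(2, 20)),) * 3 for _ in range(n)]
            refs[f"p{i}"] = self._volume_with(cells, CLASS_IRON)
            preds[f"p{i}"] = refs[f"p{i}"].copy()
        report = evaluate_cohort(preds, refs, self._cfg())
        assert report.bland_altman[CLASS_IRON]["md"] == pytest.approx(0.0)
        row = report.per_participant.iloc[0]
        assert row["ref_volume_mm3"] == row["n_ref"] * 1.5

    def test_participant_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_cohort({"a": np.zeros((4, 4, 4))},
                            {"b": np.zeros((4, 4, 4))}, self._cfg())
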
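"""Stage merging, fold plans, metrics, report averaging, significance."""

import numpy as np
import pytest

from cvmstage.evaluation import (EvalReport, assert_not_augmented,
                                 average_reports, density_preserving_subsets,
                                 evaluate, make_folds, merge_six_to_five,
                                 subset_significance)
from cvmstage.preprocess import LabeledImage


class TestMergeSixToFive:
    @pytest.mark.parametrize("six,five", [(1, 1), (2, 1), (3, 2), (4, 3),
                                          (5, 4), (6, 5)])
    def test_mapping(self, six, five):
        assert merge_six_to_five(six) == five

    def test_vectorized(self):
        np.testing.assert_array_equal(
            merge_six_to_five(np.array([1, 2, 3, 4, 5, 6])),
            np.array([1, 1, 2, 3, 4, 5]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            merge_six_to_five(0)
        with pytest.raises(ValueError):
            merge_six_to_five(np.array([1, 7]))

    def test_merged_class_counts_add(self):
        # the merged first class absorbs both of the first two stages
        counts6 = np.array([154, 187, 174, 159, 167, 177])
        labels = np.repeat(np.arange(1, 7), counts6)
        merged = merge_six_to_five(labels)
        counts5 = np.bincount(merged, minlength=6)[1:]
        assert counts5[0] == 154 + 187
        assert counts5.sum() == 1018


class TestMakeFolds:
    def _ids_labels(self, counts):
        ids, labels = [], []
        for cls, n in enumerate(counts, start=1):
            for i in range(n):
                ids.append(f"c{cls}_{i}")
                labels.append(cls)
        return ids, labels

    def test_761_images_give_printed_fold_sizes(self):
        # the training split of the study layout: 761 images over 6 stages
        counts = [115, 140, 130, 119, 125, 132]
        assert sum(counts) == 761
        ids, labels = self._ids_labels(counts)
        plan = make_folds(ids, labels, k=5, seed=0)
        assert sorted(plan.fold_sizes(), reverse=True) == [153, 152, 152, 152,
                                                           152]

    def test_stratification_within_one_image(self):
        counts = [23, 31, 18, 44, 29, 12]
        ids, labels = self._ids_labels(counts)
        plan = make_folds(ids, labels, k=5, seed=3)
        lab_of = dict(zip(ids, labels))
        for cls, n in enumerate(counts, start=1):
            per_fold = [sum(lab_of[s] == cls for s in plan.val_ids(f))
                        for f in range(5)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_same_seed_same_plan(self):
        ids, labels = self._ids_labels([10, 10, 10])
        p1 = make_folds(ids, labels, k=5, seed=9)
        p2 = make_folds(ids, labels, k=5, seed=9)
        assert p1.assignments == p2.assignments

    def test_folds_partition_the_ids(self):
        ids, labels = self._ids_labels([13, 17, 11])
        plan = make_folds(ids, labels, k=4, seed=1)
        seen = [s for f in range(4) for s in plan.val_ids(f)]
        assert sorted(seen) == sorted(ids)

    def test_class_smaller_than_k_rejected(self):
        ids, labels = self._ids_labels([3, 10])
        with pytest.raises(ValueError):
            make_folds(ids, labels, k=5, seed=0)


class _FixedProbs:
    def __init__(self, probs):
        self._p = np.asarray(probs, dtype=float)

    def predict_proba(self, images):
        return self._p


class TestEvaluate:
    def test_perfect_classifier(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        probs = np.eye(3)[y - 1]
        rep = evaluate(_FixedProbs(probs), np.zeros((6, 1)), y, num_classes=3)
        np.testing.assert_array_equal(rep.confusion, 2 * np.eye(3))
        assert rep.accuracy == 1.0
        np.testing.assert_allclose(rep.auc, 1.0)
        np.testing.assert_allclose(rep.f1, 1.0)

    def test_accuracy_equals_trace_over_total(self):
        rng = np.random.default_rng(0)
        y = rng.integers(1, 5, size=200)
        probs = rng.dirichlet(np.ones(4), size=200)
        rep = evaluate(_FixedProbs(probs), np.zeros((200, 1)), y, num_classes=4)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum(), abs=1e-12)
        np.testing.assert_array_equal(
            rep.confusion.sum(axis=1), np.bincount(y, minlength=5)[1:])

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(12)
        n = 1000
        y = np.repeat([1, 2], n // 2)
        probs = rng.dirichlet(np.ones(2), size=n)
        rep = evaluate(_FixedProbs(probs), np.zeros((n, 1)), y, num_classes=2)
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_argmax_ties_break_to_lower_class(self):
        probs = np.array([[0.4, 0.4, 0.2]])
        rep = evaluate(_FixedProbs(probs), np.zeros((1, 1)), [1], num_classes=3)
        assert rep.confusion[0, 0] == 1       # predicted class 1, not 2

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_FixedProbs(np.eye(3)), np.zeros((3, 1)), [1, 2, 4],
                     num_classes=3)

    def test_labeled_images_are_guarded_against_augmentation(self):
        img = LabeledImage(pixels=np.zeros((77, 35)), label=1, source_id="a",
                           is_augmented=True)
        with pytest.raises(ValueError):
            evaluate(_FixedProbs(np.eye(5)[:1]), [img])

    def test_assert_not_augmented_passes_originals(self):
        img = LabeledImage(pixels=np.zeros((77, 35)), label=1, source_id="a")
        assert_not_augmented([img])


class TestAverageReports:
    def _report(self, cm):
        cm = np.asarray(cm, dtype=float)
        return EvalReport(confusion=cm,
                          accuracy=float(np.trace(cm) / cm.sum()),
                          precision=np.zeros(2), recall=np.zeros(2),
                          f1=np.zeros(2), roc=None, auc=np.array([0.8, 0.9]))

    def test_identical_reports_average_to_themselves(self):
        rep = self._report([[3, 1], [0, 4]])
        avg = average_reports([rep, rep, rep])
        np.testing.assert_array_equal(avg.confusion, rep.confusion)
        assert avg.accuracy == rep.accuracy

    def test_elementwise_mean(self):
        avg = average_reports([self._report([[2, 0], [0, 2]]),
                               self._report([[0, 2], [2, 0]])])
        np.testing.assert_array_equal(avg.confusion, np.ones((2, 2)))
        assert avg.accuracy == 0.5

    def test_row_sums_are_linear(self):
        a = self._report([[5, 1], [2, 4]])
        b = self._report([[3, 3], [0, 6]])
        avg = average_reports([a, b])
        np.testing.assert_allclose(
            avg.confusion.sum(axis=1),
            (a.confusion.sum(axis=1) + b.confusion.sum(axis=1)) / 2)

    def test_shape_mismatch_rejected(self):
        a = self._report([[1, 0], [0, 1]])
        b = EvalReport(confusion=np.eye(3), accuracy=1.0,
                       precision=np.zeros(3), recall=np.zeros(3),
                       f1=np.zeros(3), roc=None, auc=None)
        with pytest.raises(ValueError):
            average_reports([a, b])


class TestSubsetSignificance:
    def test_identical_lists_give_half(self):
        acc = [0.7, 0.8, 0.75, 0.82, 0.78, 0.73, 0.8]
        res = subset_significance(acc, acc)
        assert res.p_value == pytest.approx(0.5, abs=1e-12)

    def test_extreme_separation_is_overwhelming(self):
        res = subset_significance([0.0] * 7, [1.0] * 7)
        assert res.p_value < 1e-6

    def test_means_and_stds_match_bruteforce_formulas(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(7), rng.random(7)
        res = subset_significance(a, b)
        assert res.mean_without == pytest.approx(sum(a) / 7, abs=1e-12)
        assert res.std_without == pytest.approx(
            np.sqrt(sum((a - a.mean()) ** 2) / 6), abs=1e-12)
        assert res.mean_with == pytest.approx(sum(b) / 7, abs=1e-12)
        assert res.method == "welch"

    def test_normal_overlap_mode(self):
        res = subset_significance([0.70, 0.75, 0.80], [0.85, 0.90, 0.95],
                                  method="normal-overlap")
        from scipy import stats
        expected = stats.norm.sf((0.90 - 0.75) / 0.05)
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_fewer_than_two_subsets_rejected(self):
        with pytest.raises(ValueError):
            subset_significance([0.5], [0.6])

    def test_improvement_detected_one_sided(self):
        without = [0.70, 0.72, 0.68, 0.71, 0.69, 0.73, 0.70]
        with_df = [0.80, 0.82, 0.78, 0.81, 0.79, 0.83, 0.80]
        res = subset_significance(without, with_df)
        assert res.p_value < 0.01
        worse = subset_significance(with_df, without)
        assert worse.p_value > 0.99


class TestDensitySubsets:
    def test_subsets_follow_label_density(self):
        labels = np.repeat([1, 2, 3, 4, 5], [60, 75, 70, 64, 67])
        subs = density_preserving_subsets(labels, n_subsets=7, subset_size=30,
                                          seed=1)
        assert len(subs) == 7
        for idx in subs:
            assert len(idx) == 30
            frac = np.bincount(labels[idx], minlength=6)[1:] / 30
            overall = np.bincount(labels, minlength=6)[1:] / len(labels)
            assert np.abs(frac - overall).max() < 2 / 30
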
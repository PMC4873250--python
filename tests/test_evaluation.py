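"""Confusion metrics, ROC/AUC, cross-validation plans and grid search."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hspclass import (
    ConfusionCounts,
    HspClassError,
    KernelConfig,
    auc,
    compute_metrics,
    cross_validate,
    grid_search,
    make_cv_plan,
    roc_curve,
    tally_confusion,
)


def pair_count_auc(scores, labels):
    """Independent oracle: exhaustive Mann-Whitney pair counting."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestTallyConfusion:
    def test_all_positive_agreement(self):
        c = tally_confusion([1] * 5, [1] * 5)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 0, 0, 0)

    def test_element_wise_enumeration(self):
        c = tally_confusion([1, 1, -1, -1], [1, -1, -1, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_empty_vectors_raise(self):
        with pytest.raises(HspClassError):
            tally_confusion([], [])

    def test_length_mismatch_raises(self):
        with pytest.raises(HspClassError):
            tally_confusion([1, 1], [1])

    def test_string_positive_class(self):
        c = tally_confusion(["HSP", "non"], ["HSP", "HSP"], positive_class="HSP")
        assert (c.tp, c.fp) == (1, 1)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert m.sensitivity == 100.0
        assert m.specificity == 100.0
        assert m.accuracy == 100.0
        assert m.mcc == 1.0

    def test_worked_example(self):
        # oracle: direct arithmetic on TP=50, FN=10, TN=80, FP=20
        m = compute_metrics(ConfusionCounts(tp=50, tn=80, fp=20, fn=10))
        assert abs(m.sensitivity - 100.0 * 50 / 60) < 1e-9
        assert m.specificity == 80.0
        assert m.accuracy == 81.25
        expected_mcc = (50 * 80 - 20 * 10) / math.sqrt(70 * 60 * 100 * 90)
        assert abs(m.mcc - expected_mcc) < 1e-12

    def test_empty_positive_class_gives_nan_sensitivity(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=5, fn=0))
        assert math.isnan(m.sensitivity)
        assert m.mcc == 0.0  # zero marginal convention

    def test_zero_total_raises(self):
        with pytest.raises(HspClassError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_inversion_negates_mcc(self):
        counts = ConfusionCounts(tp=30, tn=40, fp=10, fn=20)
        inverted = ConfusionCounts(tp=20, tn=10, fp=40, fn=30)
        assert abs(compute_metrics(counts).mcc + compute_metrics(inverted).mcc) < 1e-12

    def test_matches_sklearn_mcc(self):
        """Cross-check the closed-form MCC against scikit-learn's."""
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(3)
        actual = np.where(rng.random(60) > 0.4, 1, -1)
        predicted = np.where(rng.random(60) > 0.5, 1, -1)
        m = compute_metrics(tally_confusion(actual, predicted))
        assert abs(m.mcc - matthews_corrcoef(actual, predicted)) < 1e-12

    def test_sensitivity_complement_identity(self):
        c = ConfusionCounts(tp=7, tn=3, fp=2, fn=5)
        m = compute_metrics(c)
        assert abs(m.sensitivity + 100.0 * c.fn / (c.tp + c.fn) - 100.0) < 1e-9


class TestRoc:
    def test_perfect_separation_passes_through_0_1(self):
        pts = roc_curve([3.0, 2.0, -1.0, -2.0], [1, 1, -1, -1])
        assert any(np.allclose(p, [0.0, 1.0]) for p in pts)
        assert auc([3.0, 2.0, -1.0, -2.0], [1, 1, -1, -1]) == 1.0

    def test_identical_scores_give_diagonal(self):
        pts = roc_curve([0.5] * 6, [1, 1, 1, -1, -1, -1])
        np.testing.assert_allclose(pts, [[0.0, 0.0], [1.0, 1.0]])
        assert auc([0.5] * 6, [1, 1, 1, -1, -1, -1]) == 0.5

    def test_worked_stepwise_example(self):
        # pos {0.8, 0.4}, neg {0.6, 0.2}: 3 of 4 pairs ordered correctly
        scores = [0.8, 0.4, 0.6, 0.2]
        labels = [1, 1, -1, -1]
        assert auc(scores, labels) == 0.75
        assert pair_count_auc(scores, labels) == 0.75

    def test_monotone_from_origin_to_one_one(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) > 0.5, 1, -1)
        labels[:2] = [1, -1]
        pts = roc_curve(scores, labels)
        assert np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_single_class_raises(self):
        with pytest.raises(HspClassError):
            roc_curve([1.0, 2.0], [1, 1])

    def test_auc_equals_pair_counting_on_small_instances(self):
        """Trapezoid AUC = Mann-Whitney statistic, with ties and duplicates."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            labels = np.where(rng.random(n) > 0.5, 1, -1)
            if len(set(labels.tolist())) < 2:
                continue
            scores = rng.integers(0, 4, size=n).astype(float)  # heavy ties
            assert abs(auc(scores, labels) - pair_count_auc(scores, labels)) < 1e-12

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) > 0.5, 1, -1)
        labels[:2] = [1, -1]
        assert abs(auc(scores, labels) - roc_auc_score(labels, scores)) < 1e-12

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_score_negation_complements_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = np.concatenate([np.ones(10), -np.ones(10)]).astype(int)
        assert abs(auc(scores, labels) + auc(-scores, labels) - 1.0) < 1e-12


class TestCVPlan:
    def test_exact_stratification(self):
        labels = [1] * 10 + [-1] * 10
        plan = make_cv_plan(labels, "five_fold", seed=0)
        assert plan.n_folds == 5
        for fold in range(5):
            mask = plan.fold_of == fold
            assert mask.sum() == 4
            assert (np.asarray(labels)[mask] == 1).sum() == 2

    def test_stratification_within_one(self):
        labels = [1] * 13 + [-1] * 29
        plan = make_cv_plan(labels, "five_fold", seed=1)
        pos_counts = [
            (np.asarray(labels)[plan.fold_of == f] == 1).sum() for f in range(5)
        ]
        assert max(pos_counts) - min(pos_counts) <= 1

    def test_loocv_emits_n_singleton_folds(self):
        plan = make_cv_plan([1, -1, 1, -1, 1, -1, 1], "loocv")
        assert plan.n_folds == 7
        assert all((plan.fold_of == f).sum() == 1 for f in range(7))

    def test_folds_partition_the_index_set(self):
        plan = make_cv_plan([1] * 20 + [-1] * 15, "five_fold", seed=2)
        assert sorted(np.unique(plan.fold_of)) == [0, 1, 2, 3, 4]
        assert plan.fold_of.size == 35

    def test_too_small_n_raises(self):
        with pytest.raises(HspClassError):
            make_cv_plan([1, -1, 1], "five_fold")
        with pytest.raises(HspClassError):
            make_cv_plan([1], "loocv")

    def test_deterministic_given_seed(self):
        labels = [1] * 15 + [-1] * 15
        a = make_cv_plan(labels, "five_fold", seed=9)
        b = make_cv_plan(labels, "five_fold", seed=9)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)


class TestCrossValidate:
    def test_separable_set_reaches_full_accuracy(self, small_benchmark):
        records = small_benchmark.records
        labels = small_benchmark.tier1_labels
        plan = make_cv_plan(labels, "five_fold", seed=1)
        result = cross_validate(
            records, labels, "coupled", KernelConfig.linear(), plan, seed=1
        )
        assert result.pooled.accuracy >= 99.0
        assert result.pooled.auc >= 0.99

    def test_pooled_counts_conserve_n(self, small_benchmark):
        labels = small_benchmark.tier1_labels
        plan = make_cv_plan(labels, "five_fold", seed=1)
        result = cross_validate(
            small_benchmark.records, labels, "discrete",
            KernelConfig.linear(), plan, seed=1,
        )
        assert sum(c.total for c in result.per_fold) == len(labels)
        assert result.pooled_counts.total == len(labels)

    def test_shuffled_labels_give_mcc_near_zero(self, small_benchmark):
        """Permutation null: random labels carry no signal."""
        rng = np.random.default_rng(42)
        records = small_benchmark.records[:100]
        mccs = []
        for _ in range(5):
            labels = rng.permutation([1] * 50 + [-1] * 50)
            plan = make_cv_plan(labels, "five_fold", seed=0)
            result = cross_validate(
                records, labels, "discrete", KernelConfig.linear(), plan, seed=0
            )
            mccs.append(result.pooled.mcc)
        assert abs(np.mean(mccs)) < 0.15

    def test_plan_record_mismatch_raises(self, small_benchmark):
        plan = make_cv_plan([1] * 10 + [-1] * 10, "five_fold")
        with pytest.raises(HspClassError, match="plan"):
            cross_validate(
                small_benchmark.records[:5], [1, 1, 1, -1, -1], "discrete",
                KernelConfig.linear(), plan,
            )


class TestGridSearch:
    def test_single_config_grid_returns_it(self, small_benchmark):
        records = small_benchmark.records[:60]
        labels = small_benchmark.tier1_labels[:60]
        # slice keeps only HSP records; rebuild a two-class subset
        labels = np.array([1] * 30 + [-1] * 30)
        records = small_benchmark.hsp_records[:30] + small_benchmark.non_hsp_records[:30]
        plan = make_cv_plan(labels, "five_fold", seed=0)
        config = KernelConfig.rbf(gamma=0.01)
        best, table = grid_search(records, labels, "discrete", [config], plan)
        assert best == config
        assert len(table) == 1

    def test_selects_strictly_better_config(self, small_benchmark):
        records = small_benchmark.hsp_records[:30] + small_benchmark.non_hsp_records[:30]
        labels = np.array([1] * 30 + [-1] * 30)
        plan = make_cv_plan(labels, "five_fold", seed=0)
        grid = [KernelConfig.rbf(gamma=100.0), KernelConfig.linear()]
        best, table = grid_search(records, labels, "coupled", grid, plan)
        accs = table["accuracy"].to_numpy()
        assert best == grid[int(np.argmax(accs))]
        # direct comparison: the returned config has the max pooled accuracy
        assert table.loc[table["config"] == best.describe(), "accuracy"].iloc[0] == accs.max()

    def test_empty_grid_raises(self, small_benchmark):
        plan = make_cv_plan([1] * 5 + [-1] * 5, "five_fold")
        with pytest.raises(HspClassError):
            grid_search(small_benchmark.records[:10], [1] * 5 + [-1] * 5,
                        "discrete", [], plan)
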
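import warnings

import numpy as np
import pytest

from parsiopt.evaluation import (
    ConfusionByTask,
    confusion,
    cv_fitness,
    global_metrics,
    optimize_thresholds,
    stratified_kfold,
    stratified_split,
)
from parsiopt.multitask_net import TaskLabelMatrix
from parsiopt.synthetic_data import DatasetSpec, generate


class TestConfusion:
    def test_hand_counted_single_task(self):
        labels = TaskLabelMatrix(np.array([[1.0], [1.0], [0.0], [0.0]]))
        p = np.array([[0.9], [0.4], [0.6], [0.1]])
        c = confusion(labels, p, 0.5)
        assert (c.tp[0], c.fn[0], c.fp[0], c.tn[0]) == (1, 1, 1, 1)

    def test_score_equal_to_threshold_is_inactive(self):
        labels = TaskLabelMatrix(np.array([[1.0]]))
        c = confusion(labels, np.array([[0.5]]), 0.5)
        assert c.fn[0] == 1 and c.tp[0] == 0

    def test_perfect_predictions_no_errors(self, rng):
        y = rng.integers(0, 2, (30, 3)).astype(float)
        c = confusion(TaskLabelMatrix(y), np.where(y == 1, 0.9, 0.1), 0.5)
        assert c.fp.sum() == 0 and c.fn.sum() == 0

    def test_missing_cells_excluded(self):
        y = np.array([[1.0, np.nan], [0.0, 1.0]])
        c = confusion(TaskLabelMatrix(y), np.full((2, 2), 0.9), 0.5)
        assert c.tp[1] == 1 and (c.tp[1] + c.tn[1] + c.fp[1] + c.fn[1]) == 1


class TestGlobalMetrics:
    def test_all_correct_is_100(self):
        m = global_metrics(
            ConfusionByTask(np.array([5]), np.array([7]), np.array([0]), np.array([0]))
        )
        assert (m.sn, m.sp, m.ner) == (100.0, 100.0, 100.0)

    def test_hand_pooled_two_tasks(self):
        c = ConfusionByTask(
            tp=np.array([3, 1]), tn=np.array([2, 2]),
            fp=np.array([2, 2]), fn=np.array([1, 3]),
        )
        m = global_metrics(c)
        assert m.sn == pytest.approx(50.0)
        assert m.sp == pytest.approx(50.0)
        assert m.ner == pytest.approx(50.0)

    def test_task_order_irrelevant(self, rng):
        tp, tn, fp, fn = (rng.integers(0, 20, 5) for _ in range(4))
        m1 = global_metrics(ConfusionByTask(tp, tn, fp, fn))
        perm = rng.permutation(5)
        m2 = global_metrics(ConfusionByTask(tp[perm], tn[perm], fp[perm], fn[perm]))
        assert m1 == m2

    def test_pooled_oracle_on_random_tables(self, rng):
        """Pooled SN/SP/NER match an independent scalar recomputation."""
        for _ in range(1000):
            T = int(rng.integers(1, 6))
            tp, tn, fp, fn = (rng.integers(0, 50, T) for _ in range(4))
            if tp.sum() + fn.sum() == 0 or tn.sum() + fp.sum() == 0:
                continue
            m = global_metrics(ConfusionByTask(tp, tn, fp, fn))
            sn = 100 * sum(tp) / (sum(tp) + sum(fn))
            sp = 100 * sum(tn) / (sum(tn) + sum(fp))
            assert m.sn == pytest.approx(sn, abs=1e-10)
            assert m.sp == pytest.approx(sp, abs=1e-10)
            assert m.ner == pytest.approx((sn + sp) / 2, abs=1e-10)

    def test_zero_denominator_names_side(self):
        with pytest.raises(ValueError, match="active"):
            global_metrics(
                ConfusionByTask(np.array([0]), np.array([1]), np.array([1]), np.array([0]))
            )
        with pytest.raises(ValueError, match="inactive"):
            global_metrics(
                ConfusionByTask(np.array([1]), np.array([0]), np.array([0]), np.array([1]))
            )

    def test_duplicating_samples_leaves_metrics_unchanged(self, rng):
        y = rng.integers(0, 2, (20, 2)).astype(float)
        p = rng.random((20, 2))
        m1 = global_metrics(confusion(TaskLabelMatrix(y), p, 0.5))
        m2 = global_metrics(
            confusion(TaskLabelMatrix(np.vstack([y, y])), np.vstack([p, p]), 0.5)
        )
        assert m1 == m2


class TestOptimizeThresholds:
    def test_separated_scores_reach_perfect_balanced_accuracy(self):
        y = np.array([[1.0], [1.0], [0.0], [0.0]])
        p = np.array([[0.9], [0.8], [0.2], [0.1]])
        labels = TaskLabelMatrix(y)
        thr = optimize_thresholds(labels, p)
        c = confusion(labels, p, thr)
        assert global_metrics(c).ner == 100.0

    def test_matches_brute_force_oracle(self, rng):
        """Exhaustive scan over all candidate cuts on random tasks."""
        for _ in range(20):
            y = rng.integers(0, 2, 50).astype(float)
            if y.sum() in (0, 50):
                continue
            s = np.round(rng.random(50), 3)
            labels = TaskLabelMatrix(y[:, None])
            thr = optimize_thresholds(labels, s[:, None])
            su = np.unique(s)
            cands = np.concatenate(([0.0], (su[:-1] + su[1:]) / 2, [1.0]))

            def ba(c):
                sens = ((y == 1) & (s > c)).sum() / (y == 1).sum()
                spec = ((y == 0) & (s <= c)).sum() / (y == 0).sum()
                return (sens + spec) / 2

            best = max(ba(c) for c in cands)
            assert ba(thr[0]) == pytest.approx(best, abs=1e-12)

    def test_constant_scores_give_half(self):
        labels = TaskLabelMatrix(np.array([[1.0], [0.0]]))
        thr = optimize_thresholds(labels, np.full((2, 1), 0.7))
        # constant scores: no cut separates; smallest tied threshold wins
        assert 0.0 <= thr[0] <= 1.0

    def test_single_class_task_warns_and_returns_half(self):
        labels = TaskLabelMatrix(np.array([[1.0], [1.0]]))
        with pytest.warns(UserWarning, match="single-class"):
            thr = optimize_thresholds(labels, np.array([[0.3], [0.9]]))
        assert thr[0] == 0.5


class TestStratifiedSplit:
    def test_balanced_single_task_80_20(self):
        y = np.array([1.0] * 500 + [0.0] * 500)[:, None]
        tr, te = stratified_split(TaskLabelMatrix(y), 0.2, seed=0)
        assert len(tr) == 800 and len(te) == 200
        assert abs(y[tr].mean() - 0.5) <= 1 / 800
        assert abs(y[te].mean() - 0.5) <= 1 / 200

    def test_partition_exact_and_disjoint(self, rng):
        y = rng.integers(0, 2, (333, 3)).astype(float)
        tr, te = stratified_split(TaskLabelMatrix(y), 0.2, seed=1)
        assert np.array_equal(np.sort(np.concatenate([tr, te])), np.arange(333))

    def test_same_seed_same_split(self, rng):
        y = rng.integers(0, 2, (100, 2)).astype(float)
        a = stratified_split(TaskLabelMatrix(y), 0.2, seed=5)
        b = stratified_split(TaskLabelMatrix(y), 0.2, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_imbalanced_multilabel_prevalence_preserved(self):
        spec = DatasetSpec(
            n_samples=1472, n_tasks=2, prevalence=(0.941, 0.071),
            missing_fraction=(0.0, 0.0), task_correlation=0.3, seed=0,
        )
        _, labels = generate(spec)
        tr, _ = stratified_split(labels, 0.2, seed=0)
        full = np.nanmean(labels.values, axis=0)
        train_prev = np.nanmean(labels.values[tr], axis=0)
        assert np.all(np.abs(train_prev - full) < 0.02)

    def test_kfold_covers_everything_once(self, rng):
        y = rng.integers(0, 2, (90, 2)).astype(float)
        folds = stratified_kfold(TaskLabelMatrix(y), 3, seed=0)
        allidx = np.sort(np.concatenate(folds))
        assert np.array_equal(allidx, np.arange(90))
        assert {len(f) for f in folds} == {30}


class TestCvFitness:
    def test_separable_data_high_ner(self, good_arch):
        spec = DatasetSpec(
            n_samples=2000, n_tasks=1, prevalence=(0.35,),
            missing_fraction=(0.0,), task_correlation=0.0,
            signal_scale=np.inf, signal_kind="count", seed=0,
        )
        X, y = generate(spec)
        m = cv_fitness(X, y, good_arch, k=3, seed=0)
        assert m.ner >= 90.0

    def test_deterministic_given_seed(self, good_arch):
        spec = DatasetSpec(
            n_samples=200, n_tasks=1, prevalence=(0.4,),
            missing_fraction=(0.0,), task_correlation=0.0, seed=1,
        )
        X, y = generate(spec)
        m1 = cv_fitness(X, y, good_arch, k=3, seed=3)
        m2 = cv_fitness(X, y, good_arch, k=3, seed=3)
        assert m1 == m2
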
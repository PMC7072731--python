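"""Metric formulas against independent recomputation; CV protocol contracts."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from ubp_pred.classifier import train
from ubp_pred.evaluation import (
    ConfusionCounts,
    MetricSet,
    compute_metrics,
    independent_test,
    kfold_cv,
    mean_metrics,
)


def brute_force_metrics(y_true, y_pred):
    """Independent recomputation straight from label/call pairs."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = ((y_true == 1) & (y_pred == 1)).sum()
    fp = ((y_true == 0) & (y_pred == 1)).sum()
    tn = ((y_true == 0) & (y_pred == 0)).sum()
    fn = ((y_true == 1) & (y_pred == 0)).sum()
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / len(y_true)
    f1 = 2 * sen * pre / (sen + pre) if sen + pre else 0.0
    mcc = matthews_corrcoef(y_true, y_pred) if len(set(y_true)) > 1 else 0.0
    return sen, spe, pre, acc, f1, mcc


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert m == MetricSet(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_total_inversion(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=5, tn=0, fn=5))
        assert m.acc == 0.0
        assert m.mcc == -1.0

    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=2, fn=2))
        assert m.sen == pytest.approx(0.600)
        assert m.spe == pytest.approx(2 / 3)
        assert m.pre == pytest.approx(0.750)
        assert m.acc == pytest.approx(0.625)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.mcc == pytest.approx(0.2581988897)

    def test_against_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fp + tn + fn == 0:
                continue
            y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
            y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
            m = compute_metrics(ConfusionCounts.from_pairs(y_true, y_pred))
            sen, spe, pre, acc, f1, mcc = brute_force_metrics(y_true, y_pred)
            assert m.sen == pytest.approx(sen)
            assert m.spe == pytest.approx(spe)
            assert m.pre == pytest.approx(pre)
            assert m.acc == pytest.approx(acc)
            assert m.f1 == pytest.approx(f1)
            # sklearn reports MCC 0 on degenerate tables, same convention
            assert m.mcc == pytest.approx(mcc, abs=1e-12)

    def test_mcc_symmetric_under_class_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 20, size=4))
            if tp + fp + tn + fn == 0:
                continue
            a = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
            b = compute_metrics(ConfusionCounts(tp=tn, fp=fn, tn=tp, fn=fp))
            assert a.mcc == pytest.approx(b.mcc)
            assert a.acc == pytest.approx(b.acc)
            assert a.sen == pytest.approx(b.spe)
            assert a.spe == pytest.approx(b.sen)

    def test_zero_samples_is_error(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestKfoldCv:
    def test_stratified_balanced_folds(self, separable_matrix):
        from sklearn.model_selection import StratifiedKFold

        y = separable_matrix.labels
        for _, test_idx in StratifiedKFold(5, shuffle=True, random_state=0).split(
            separable_matrix.values, y
        ):
            assert len(test_idx) == 40
            assert y[test_idx].sum() == 20

    def test_fixed_seed_reproducible(self, separable_matrix):
        trainer = lambda m: train(m, seed=0, nthread=1)
        a, folds_a = kfold_cv(separable_matrix, trainer, k=5, seed=3)
        b, folds_b = kfold_cv(separable_matrix, trainer, k=5, seed=3)
        assert a == b
        assert folds_a == folds_b

    def test_separable_dataset_high_mcc(self, separable_matrix):
        trainer = lambda m: train(m, seed=0, nthread=1)
        mean, per_fold = kfold_cv(separable_matrix, trainer, k=5, seed=0)
        assert len(per_fold) == 5
        assert mean.mcc >= 0.9

    def test_repeats_multiply_folds(self, separable_matrix):
        trainer = lambda m: train(m, seed=0, nthread=1)
        _, per_fold = kfold_cv(separable_matrix, trainer, k=5, repeats=2, seed=0)
        assert len(per_fold) == 10

    def test_unlabeled_matrix_is_error(self, separable_matrix):
        unlabeled = type(separable_matrix)(
            separable_matrix.ids, separable_matrix.names, separable_matrix.values
        )
        with pytest.raises(ValueError, match="labels"):
            kfold_cv(unlabeled, lambda m: None)


class TestIndependentTest:
    def test_model_on_own_training_set_is_perfect(self, separable_matrix):
        model = train(separable_matrix, seed=0, nthread=1)
        metrics = independent_test(model, separable_matrix)
        assert metrics.mcc == 1.0

    def test_id_overlap_is_leakage_error(self, separable_matrix):
        model = train(separable_matrix, seed=0, nthread=1)
        with pytest.raises(ValueError, match="train_test_leakage"):
            independent_test(model, separable_matrix, train_ids={"s000"})

    def test_empty_test_set_is_error(self, separable_matrix):
        model = train(separable_matrix, seed=0, nthread=1)
        empty = type(separable_matrix)(
            [], separable_matrix.names, np.empty((0, separable_matrix.d)), np.empty(0, int)
        )
        with pytest.raises(ValueError, match="empty"):
            independent_test(model, empty)


def test_mean_metrics_componentwise():
    a = MetricSet(1.0, 0.0, 1.0, 0.5, 0.5, 0.0)
    b = MetricSet(0.0, 1.0, 0.0, 0.5, 0.5, 1.0)
    m = mean_metrics([a, b])
    assert m == MetricSet(0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
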
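"""Confusion-matrix metrics and the cross-validation / independent-test protocol.

Six binary-classification measurements are reported throughout: sensitivity
(Sen), specificity (Spe), precision (Pre), accuracy (ACC), F1-measure and
the Matthews correlation coefficient (MCC).  MCC is treated as the primary
model-selection metric: it uses all four confusion counts and is robust to
class balance, which matters because feature selection and hyperparameter
tuning both select on it.

Degenerate denominators follow the common convention: a ratio with a zero
denominator is reported as 0, and MCC with any zero factor under the square
root is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from ubp_pred.features import FeatureMatrix


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts from a binary evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_pairs(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must align")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    """Sen, Spe, Pre, ACC, F1 in [0, 1] and MCC in [-1, 1]."""

    sen: float
    spe: float
    pre: float
    acc: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def objective_values(self, objectives: tuple[str, ...]) -> tuple[float, ...]:
        """Extract a named subset of metrics (all maximized) for the tuner."""
        return tuple(getattr(self, name) for name in objectives)


METRIC_NAMES = ("sen", "spe", "pre", "acc", "f1", "mcc")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The six measurements from a confusion count.

    Sen = TP/(TP+FN); Spe = TN/(TN+FP); Pre = TP/(TP+FP);
    ACC = (TP+TN)/total; F1 = 2*Sen*Pre/(Sen+Pre);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, fp, tn, fn = float(c.tp), float(c.fp), float(c.tn), float(c.fn)
    sen = _ratio(tp, tp + fn)
    spe = _ratio(tn, tn + fp)
    pre = _ratio(tp, tp + fp)
    acc = (tp + tn) / c.total
    f1 = _ratio(2.0 * sen * pre, sen + pre)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricSet(sen=sen, spe=spe, pre=pre, acc=acc, f1=f1, mcc=mcc)


def mean_metrics(sets: list[MetricSet]) -> MetricSet:
    """Component-wise mean of per-fold metric sets."""
    if not sets:
        raise ValueError("no metric sets to average")
    return MetricSet(
        **{k: float(np.mean([getattr(m, k) for m in sets])) for k in METRIC_NAMES}
    )


def kfold_cv(
    matrix: FeatureMatrix,
    trainer: Callable[[FeatureMatrix], object],
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> tuple[MetricSet, list[MetricSet]]:
    """Stratified k-fold cross-validation, optionally repeated.

    ``trainer`` maps a training FeatureMatrix to a fitted model exposing the
    :func:`ubp_pred.classifier.predict` contract.  With ``repeats`` r, the
    k folds are re-drawn r times (r * k submodels); the mean over all
    held-out folds is returned alongside the per-fold metrics.  Stratified
    splitting keeps both classes in every fold; a fold missing a class is an
    error, indicating the dataset is too small for k folds.
    """
    from ubp_pred.classifier import predict  # local import to avoid a cycle

    if matrix.labels is None:
        raise ValueError("cross-validation requires labels")
    if k < 2:
        raise ValueError("k must be >= 2")
    y = matrix.labels
    if repeats == 1:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    per_fold: list[MetricSet] = []
    for train_idx, test_idx in splitter.split(matrix.values, y):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError("a cross-validation fold lost a class; dataset too small")
        model = trainer(matrix.select_rows(train_idx))
        _, calls = predict(model, matrix.select_rows(test_idx))
        per_fold.append(compute_metrics(ConfusionCounts.from_pairs(y[test_idx], calls)))
    return mean_metrics(per_fold), per_fold


def independent_test(
    model: object,
    test_matrix: FeatureMatrix,
    train_ids: set[str] | None = None,
) -> MetricSet:
    """Evaluate a fitted model on a held-out labeled set.

    When ``train_ids`` is given, any overlap with the test ids raises
    ``train_test_leakage`` — the independent test exists to measure
    performance on first-seen samples.
    """
    from ubp_pred.classifier import predict

    if test_matrix.n == 0:
        raise ValueError("empty test set")
    if test_matrix.labels is None:
        raise ValueError("independent test requires labels")
    if train_ids is not None:
        overlap = set(test_matrix.ids) & set(train_ids)
        if overlap:
            raise ValueError(
                f"train_test_leakage: {len(overlap)} ids appear in both sets "
                f"(e.g. {sorted(overlap)[:3]})"
            )
    _, calls = predict(model, test_matrix)
    return compute_metrics(ConfusionCounts.from_pairs(test_matrix.labels, calls))
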
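"""Random-forest importance ranking and incremental feature selection (IFS).

The composition/profile encoding is deliberately exhaustive (all residues,
all pairs, all residue-column combinations), so many features carry noise or
redundancy.  Selection proceeds in two stages:

1. **Ranking.** A random forest is fit on the labeled matrix and each
   feature is scored by its mean decrease in Gini impurity across the
   forest; larger scores rank higher.  Features whose importance is exactly
   zero never split a node and are dropped.
2. **IFS.** Nested prefixes of the ranking (top-1, top-2, ...) are each
   evaluated by cross-validated classification, and the prefix maximizing
   cross-validated MCC becomes the optimal feature subset (smallest prefix
   wins ties, favoring parsimony).

Ties in importance are broken by original column index, so the ranking is
deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ubp_pred.evaluation import MetricSet, kfold_cv
from ubp_pred.features import FeatureMatrix

DEFAULT_N_TREES = 500


@dataclass
class RankedFeatures:
    """Importance-ordered features: (name, importance) non-increasing."""

    ranking: list[tuple[str, float]]

    def __post_init__(self) -> None:
        imps = [imp for _, imp in self.ranking]
        if any(imp < 0 for imp in imps):
            raise ValueError("importances must be non-negative")
        if any(a < b for a, b in zip(imps, imps[1:])):
            raise ValueError("ranking must be non-increasing in importance")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.ranking]

    @property
    def n_nonzero(self) -> int:
        return sum(1 for _, imp in self.ranking if imp > 0)

    def __len__(self) -> int:
        return len(self.ranking)


@dataclass
class IfsTrace:
    """The IFS evaluation trace over nested prefixes of a ranking."""

    steps: list[tuple[int, float]]  # (subset_size, cv MCC)
    best_size: int
    best_subset: list[str]
    per_step_metrics: list[MetricSet] = field(default_factory=list)


def rank_features(
    matrix: FeatureMatrix,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> RankedFeatures:
    """Rank features by mean Gini-impurity decrease over a random forest.

    Deterministic for a fixed seed: the forest is seeded and ties are broken
    by original column index (stable sort on descending importance).
    """
    if matrix.labels is None:
        raise ValueError("ranking requires labels")
    classes, counts = np.unique(matrix.labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ranking requires both classes present")
    if counts.min() < 2:
        raise ValueError("ranking requires at least 2 samples per class")
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    )
    forest.fit(matrix.values, matrix.labels)
    importances = forest.feature_importances_
    order = np.lexsort((np.arange(len(importances)), -importances))
    return RankedFeatures(
        [(matrix.names[i], float(importances[i])) for i in order]
    )


def drop_zero_importance(ranked: RankedFeatures) -> RankedFeatures:
    """Retain only strictly positive importances.

    Zero-importance features were never chosen to split any node of the
    forest and carry no ranking information.  An all-zero ranking returns an
    empty result with a warning (degenerate input: the forest found no
    informative split anywhere).
    """
    kept = [(name, imp) for name, imp in ranked.ranking if imp > 0]
    if not kept:
        warnings.warn("all feature importances are zero; nothing retained")
    return RankedFeatures(kept)


def incremental_feature_selection(
    matrix: FeatureMatrix,
    ranked: RankedFeatures,
    evaluator: Callable[[FeatureMatrix], MetricSet],
    max_size: int | None = None,
    step: int = 1,
) -> IfsTrace:
    """Evaluate nested prefixes of the ranking; keep the MCC-maximizing one.

    For k = 1..min(max_size, len(ranked)) in increments of ``step``, the
    matrix restricted to the top-k features is passed to ``evaluator``
    (typically cross-validated training; see :func:`make_cv_evaluator`).
    The prefix with the highest MCC wins; the smallest k wins ties.
    An evaluator failure aborts with the offending k reported.
    """
    if len(ranked) == 0:
        raise ValueError("ranking is empty")
    if step < 1:
        raise ValueError("step must be >= 1")
    limit = len(ranked) if max_size is None else min(max_size, len(ranked))
    names = ranked.names
    steps: list[tuple[int, float]] = []
    metrics: list[MetricSet] = []
    for k in range(1, limit + 1, step):
        sub = matrix.select_features(names[:k])
        try:
            metric = evaluator(sub)
        except Exception as exc:
            raise RuntimeError(f"IFS evaluator failed at subset size {k}: {exc}") from exc
        steps.append((k, metric.mcc))
        metrics.append(metric)
    best_idx = int(np.argmax([mcc for _, mcc in steps]))  # argmax takes first on ties
    best_size = steps[best_idx][0]
    return IfsTrace(
        steps=steps,
        best_size=best_size,
        best_subset=names[:best_size],
        per_step_metrics=metrics,
    )


def make_cv_evaluator(
    params=None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> Callable[[FeatureMatrix], MetricSet]:
    """Cross-validated XGBoost evaluator for IFS and tuning.

    Returns a callable mapping a labeled FeatureMatrix to the mean MetricSet
    over stratified k-fold cross-validation with the given hyperparameters
    (defaults when ``params`` is None).
    """
    from ubp_pred.classifier import train

    def evaluate(sub: FeatureMatrix) -> MetricSet:
        mean, _ = kfold_cv(
            sub,
            trainer=lambda m: train(m, params=params, seed=seed, nthread=1),
            k=k,
            repeats=repeats,
            seed=seed,
        )
        return mean

    return evaluate
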
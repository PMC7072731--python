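"""The XGBoost binary model under an explicit eight-parameter configuration.

The classifier is a gradient-boosted decision-tree ensemble (tree booster
only).  Eight hyperparameters are exposed for tuning, each with a default and
a search interval:

==================  =======  ===========
parameter           default  interval
==================  =======  ===========
learning_rate       0.10     [0, 0.5]
n_estimators        100      [100, 2000]
max_depth           3        [1, 10]
subsample           1.00     (0, 1]
colsample_bytree    1.00     (0, 1]
gamma               0        [0, 1]
reg_alpha           0        [0, 1]
reg_lambda          1.00     [0, 2]
==================  =======  ===========

Training goes through ``xgboost.train`` with the binary logistic objective;
class calls use a 0.5 probability threshold.  Predictions are aligned to the
training feature names, so column order at predict time is a name-based
contract, not a positional one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import xgboost as xgb

from ubp_pred.features import FeatureMatrix

#: (low, high, is_integer) search bounds per tunable parameter, in a fixed order.
PARAM_BOUNDS: dict[str, tuple[float, float, bool]] = {
    "learning_rate": (0.0, 0.5, False),
    "n_estimators": (100, 2000, True),
    "max_depth": (1, 10, True),
    "subsample": (0.0, 1.0, False),
    "colsample_bytree": (0.0, 1.0, False),
    "gamma": (0.0, 1.0, False),
    "reg_alpha": (0.0, 1.0, False),
    "reg_lambda": (0.0, 2.0, False),
}

PARAM_ORDER = tuple(PARAM_BOUNDS)

CLASSIFICATION_THRESHOLD = 0.5


@dataclass(frozen=True)
class HyperParams:
    """The eight-dimensional XGBoost configuration; tree booster fixed."""

    learning_rate: float = 0.10
    n_estimators: int = 100
    max_depth: int = 3
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    gamma: float = 0.0
    reg_alpha: float = 0.0
    reg_lambda: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> bool:
        for name, (low, high, is_int) in PARAM_BOUNDS.items():
            value = getattr(self, name)
            if not (low <= value <= high):
                raise ValueError(f"{name}={value} outside [{low}, {high}]")
            if is_int and int(value) != value:
                raise ValueError(f"{name}={value} must be an integer")
        if self.subsample == 0 or self.colsample_bytree == 0:
            raise ValueError("subsample and colsample_bytree must be > 0")
        return True

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_vector(cls, position: np.ndarray) -> "HyperParams":
        """Build from an 8-vector in :data:`PARAM_ORDER`, rounding integers."""
        kwargs = {}
        for name, value in zip(PARAM_ORDER, position):
            if PARAM_BOUNDS[name][2]:
                kwargs[name] = int(round(float(value)))
            else:
                kwargs[name] = float(value)
        return cls(**kwargs)

    def to_xgb_params(self, seed: int = 0, nthread: int | None = None) -> dict:
        params = {
            "objective": "binary:logistic",
            "booster": "gbtree",
            "tree_method": "hist",
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "gamma": self.gamma,
            "alpha": self.reg_alpha,
            "lambda": self.reg_lambda,
            "seed": seed,
        }
        if nthread is not None:
            params["nthread"] = nthread
        return params


def default_params() -> HyperParams:
    """The untuned configuration (all fields at their defaults)."""
    return HyperParams()


@dataclass
class TrainedModel:
    """A fitted booster plus the metadata needed to apply it safely."""

    booster: xgb.Booster
    params: HyperParams
    feature_names: list[str]
    seed: int
    n_train: int

    def save(self, path: str | Path) -> None:
        """Serialize to a single JSON artifact (portable, text-only)."""
        payload = {
            "params": self.params.as_dict(),
            "feature_names": self.feature_names,
            "seed": self.seed,
            "n_train": self.n_train,
            "booster": json.loads(self.booster.save_raw("json").decode()),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]), "utf-8"))
        return cls(
            booster=booster,
            params=HyperParams(**payload["params"]),
            feature_names=list(payload["feature_names"]),
            seed=int(payload["seed"]),
            n_train=int(payload["n_train"]),
        )


def train(
    matrix: FeatureMatrix,
    params: HyperParams | None = None,
    seed: int = 0,
    nthread: int | None = None,
) -> TrainedModel:
    """Fit the boosted-tree model on a labeled feature matrix.

    Deterministic for a fixed seed and a fixed thread count (pass
    ``nthread=1`` for bit-reproducibility; ``None`` leaves the thread count
    at the library default for speed).
    """
    if params is None:
        params = default_params()
    if matrix.labels is None:
        raise ValueError("training requires labels")
    classes = np.unique(matrix.labels)
    if len(classes) < 2:
        raise ValueError("training requires both classes present")
    dtrain = xgb.DMatrix(matrix.values, label=matrix.labels, feature_names=matrix.names)
    booster = xgb.train(
        params.to_xgb_params(seed=seed, nthread=nthread),
        dtrain,
        num_boost_round=params.n_estimators,
    )
    return TrainedModel(
        booster=booster,
        params=params,
        feature_names=list(matrix.names),
        seed=seed,
        n_train=matrix.n,
    )


def predict(
    model: TrainedModel,
    matrix: FeatureMatrix,
    threshold: float = CLASSIFICATION_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample probability of class 1 and 0/1 calls at ``threshold``.

    Input columns are realigned to the training feature names by name;
    missing or extra columns are an error listing the offenders.
    """
    if set(matrix.names) != set(model.feature_names):
        missing = sorted(set(model.feature_names) - set(matrix.names))
        extra = sorted(set(matrix.names) - set(model.feature_names))
        raise ValueError(
            f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}"
        )
    if matrix.names != model.feature_names:
        matrix = matrix.select_features(model.feature_names)
    dtest = xgb.DMatrix(matrix.values, feature_names=matrix.names)
    proba = model.booster.predict(dtest)
    calls = (proba >= threshold).astype(int)
    return proba, calls
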
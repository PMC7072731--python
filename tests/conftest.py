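"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from ubp_pred.features import FeatureMatrix
from ubp_pred.io_formats import ProteinRecord
from ubp_pred.synthetic import SyntheticConfig, generate_labeled_dataset


@pytest.fixture(scope="session")
def planted_matrix() -> FeatureMatrix:
    """A 60-sample labeled matrix with strong compositional class signal."""
    config = SyntheticConfig(
        seed=11, n_pos=30, n_neg=30, signal_kind="aac_bias", effect_size=0.8
    )
    return generate_labeled_dataset(config)


@pytest.fixture(scope="session")
def separable_matrix() -> FeatureMatrix:
    """A linearly separable 10-feature dataset (n=200) for classifier tests."""
    rng = np.random.default_rng(5)
    n, d = 200, 10
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, d))
    X[:, 0] += 6.0 * y  # feature f0 fully determines the class
    ids = [f"s{i:03d}" for i in range(n)]
    names = [f"f{j}" for j in range(d)]
    return FeatureMatrix(ids, names, X, y)


@pytest.fixture
def toy_records() -> list[ProteinRecord]:
    return [
        ProteinRecord("p1", "ACDEFGHIKLMNPQRSTVWY" * 3),
        ProteinRecord("p2", "MKV" + "A" * 60),
    ]
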
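import numpy as np
import pytest

from deepens import CLUSpec, FeatureTable, SplitSpec, apply_standard_scaler, fit_standard_scaler, split_dataset
from deepens.synthetic import StatisticalGenSpec, gen_statistical


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_xy(rng):
    """Linearly separable 2-feature data with a wide margin."""
    n = 200
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(scale=0.3, size=(n, 2))
    X[:, 0] += 3.0 * y - 1.5
    order = rng.permutation(n)
    return X[order], y[order]


@pytest.fixture
def small_mlp_spec():
    return CLUSpec(kind="mlp", layer_sizes=(8, 1), epochs=30, seed=7, initial_lr=0.01)


@pytest.fixture
def planted_table():
    """Strong planted-signal tabular dataset (near-1 Bayes accuracy)."""
    return gen_statistical(StatisticalGenSpec(n_samples=500, n_features=10, n_informative=4, effect_size=3.0, missing_rate=0.0, seed=11))


def scaled_fold(table: FeatureTable, seed: int = 0):
    """Impute-free standardised (train, val, test) arrays from fold 0."""
    train_idx, val_idx, test_idx = split_dataset(table.n, SplitSpec(seed=seed))[0]
    scaler = fit_standard_scaler(table.subset(train_idx))
    X = apply_standard_scaler(scaler, table).values
    y = table.labels
    return (
        (X[train_idx], y[train_idx]),
        (X[val_idx], y[val_idx]),
        (X[test_idx], y[test_idx]),
    )
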
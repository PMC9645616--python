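import numpy as np
import pytest

from perfcast.simdata import LabeledDataset, PartConfig, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_part():
    """A small discriminating part for fast unit tests."""
    return PartConfig(
        num_datasets=5, n_train=40, n_group1=20, n_features=12,
        n_rep=3, sd_tech=1.0, sd_biol=1.0, diff_expr=True, fold_min=2.0,
    )


@pytest.fixture
def small_config(small_part):
    from dataclasses import replace

    noise = replace(small_part, n_features=8, diff_expr=False)
    return SimulationConfig(name="toy", parts=(small_part, noise), seed=7)


@pytest.fixture
def blob_dataset(rng):
    """Two well-separated Gaussian blobs: trivially classifiable."""
    n_half = 20
    X = np.vstack([
        rng.normal(0.0, 0.5, size=(n_half, 6)),
        rng.normal(6.0, 0.5, size=(n_half, 6)),
    ])
    y = np.repeat([1, 0], n_half)
    return LabeledDataset(X=X, y=y, feature_names=[f"g{i}" for i in range(6)],
                          name="blobs")


@pytest.fixture
def noise_dataset(rng):
    """Pure-noise dataset: labels carry no information."""
    X = rng.normal(size=(40, 15))
    y = np.repeat([1, 0], 20)
    return LabeledDataset(X=X, y=y, feature_names=[f"g{i}" for i in range(15)],
                          name="noise")
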
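import numpy as np
import pandas as pd
import pytest

from pddlearn.discretize import CategoricalDataset
from pddlearn.pipeline import PDD
from pddlearn.synth import SyntheticSpec, generate


def make_dataset(rows, label="class", ids=None):
    """Build a CategoricalDataset from a list of dicts."""
    df = pd.DataFrame(rows)
    if ids is None:
        ids = [f"r{i}" for i in range(len(df))]
    df.index = pd.Index(ids, name="record_id")
    return CategoricalDataset(df, label_attribute=label)


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world: 2000 records, 24.4% minority, 10%
    mislabels, 1% outliers, 2% ambiguous, signal strength 0.6."""
    spec = SyntheticSpec(seed=0)
    dataset, truth = generate(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def fitted_default(default_world):
    """PDD fitted on the default world (shared across tests)."""
    _, dataset, _ = default_world
    X = dataset.data[dataset.feature_attributes]
    y = dataset.labels()
    return PDD().fit(X, y)


@pytest.fixture(scope="session")
def small_world():
    """A small, fast synthetic world for pipeline-level unit tests."""
    spec = SyntheticSpec(n_records=400, n_signal_attrs=5, n_noise_attrs=3,
                         seed=7)
    dataset, truth = generate(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
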
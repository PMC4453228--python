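import numpy as np
import pytest

from uncles.expression_io import ExpressionDataset
from uncles.synthetic_data import SyntheticConfig, generate


def make_dataset(values, dataset_id="d", role="unspecified",
                 channel="unknown", gene_ids=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i+1}" for i in range(values.shape[0])]
    return ExpressionDataset(dataset_id=dataset_id, gene_ids=gene_ids,
                             values=values, role=role, channel=channel)


@pytest.fixture
def two_clouds():
    """40 well-separated 3-sample profiles in two groups of 20."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.1, (20, 3)) + np.array([0.0, 5.0, 10.0])
    b = rng.normal(0.0, 0.1, (20, 3)) + np.array([10.0, 5.0, 0.0])
    return make_dataset(np.vstack([a, b]), dataset_id="clouds")


@pytest.fixture(scope="session")
def small_collection():
    """A small planted six-dataset collection for engine-level tests."""
    return generate(SyntheticConfig(gs=300, seed=11))
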
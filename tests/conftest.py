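import numpy as np
import pytest
from sklearn.datasets import make_blobs

from gnetox.synthetic import SyntheticConfig, generate_assay_data, generate_bundle


def scaled_blobs(n, random_state):
    """Two separable Gaussian blobs, min-max scaled to [0, 1]."""
    X, y = make_blobs(n_samples=n, centers=2, cluster_std=1.0,
                      random_state=random_state)
    X = (X - X.min(axis=0)) / (X.max(axis=0) - X.min(axis=0))
    return X, y


@pytest.fixture(scope="session")
def blobs40():
    return scaled_blobs(40, 1)


@pytest.fixture(scope="session")
def blobs60():
    return scaled_blobs(60, 2)


@pytest.fixture(scope="session")
def small_table():
    """Small planted-signal assay table for fast classifier tests."""
    cfg = SyntheticConfig(n_compounds=150, n_assays=3, n_physchem=8,
                          n_fingerprints=12, n_informative=5,
                          missing_frac=0.0, seed=21)
    table, record = generate_assay_data(cfg)
    return table, record


@pytest.fixture(scope="session")
def raw_bundle():
    """Raw synthetic bundle with missingness, for curation tests."""
    cfg = SyntheticConfig(n_compounds=120, n_assays=6, n_physchem=10,
                          n_fingerprints=20, n_informative=5,
                          missing_frac=0.08, seed=33)
    return cfg, generate_bundle(cfg)
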
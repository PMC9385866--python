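import numpy as np
import pytest

from finnet import MLPConfig, SyntheticSpec, generate_features, train_mlp


@pytest.fixture(scope="session")
def blob_data():
    """Well-separated 5-class blobs (separation 8 sd) plus labels."""
    spec = SyntheticSpec(
        n_cases=500, n_classes=5, n_features=10, separation=8.0, within_class_sd=1.0, seed=42
    )
    features, labels = generate_features(spec)
    return spec, features, labels


@pytest.fixture(scope="session")
def trained_mlp(blob_data):
    """A small trained MLP on the blob fixture (shared across tests)."""
    _, features, labels = blob_data
    config = MLPConfig(hidden_units=15, max_epochs=100, weight_decay=1e-3, seed=0)
    return train_mlp(features, labels, config), features, labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
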
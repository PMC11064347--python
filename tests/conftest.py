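import numpy as np
import pytest

from latemix.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-sample cohort with modest block widths, shared across tests."""
    return simulate_cohort(SimConfig(n_samples=300, block_sizes=(60, 25, 12),
                                     seed=42))


@pytest.fixture(scope="session")
def train_mask(small_cohort):
    return (small_cohort.split == "train").to_numpy()


@pytest.fixture(scope="session")
def blob_features():
    """Linearly separable 3-class blobs: 600 samples, 5 features, labels in
    {-1, 0, +1} with realistic 15/70/15 imbalance."""
    rng = np.random.default_rng(7)
    n = 600
    labels = rng.choice([-1, 0, 1], size=n, p=[0.15, 0.70, 0.15])
    centers = {-1: np.array([-4.0, 0, 0, 0, 0]),
               0: np.zeros(5),
               1: np.array([4.0, 0, 0, 0, 0])}
    X = np.stack([centers[c] for c in labels]) + rng.normal(0, 0.8, (n, 5))
    return X, labels
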
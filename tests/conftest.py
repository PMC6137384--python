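import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rnncluster as rnc

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


class FixedModel:
    """A stub classifier that replays preset +/-1 predictions."""

    def __init__(self, preds):
        self.preds = np.asarray(preds, dtype=int)

    def predict(self, X):
        return self.preds[: len(X)]


def stub_learner(preds, feature_indices=(0,)):
    return rnc.BaseLearner(
        feature_indices=np.asarray(feature_indices, dtype=int),
        sample_indices=np.arange(1),
        model=FixedModel(preds),
    )


def stub_cluster(vote_matrix, n_features=3):
    """Cluster of stub learners; vote_matrix is (k, n_subjects) of +/-1."""
    learners = [stub_learner(row) for row in np.asarray(vote_matrix)]
    cfg = rnc.ClusterConfig(k=len(learners), n_samples=1, m_features=1, seed=0)
    return rnc.NetworkCluster(learners=learners, config=cfg, feature_universe_size=n_features)


@pytest.fixture
def small_atlas():
    return rnc.synthetic_atlas(6)


@pytest.fixture
def toy_dataset():
    """Linearly separable 2-feature dataset, balanced classes."""
    rng = np.random.default_rng(7)
    n = 24
    y = np.repeat([1, -1], n // 2)
    X = rng.normal(size=(n, 2))
    X[:, 0] += 3.0 * y
    return rnc.LabeledDataset(
        features=X, labels=y, subject_ids=tuple(f"s{i}" for i in range(n))
    )


@pytest.fixture
def planted_features_dataset():
    """Fast FC-like dataset with a strong planted signal (small universe)."""
    cfg = rnc.SyntheticConfig(
        R=20, n_group_pos=16, n_group_neg=14, planted_edges=8, delta=0.5, seed=11
    )
    return rnc.simulate_feature_matrix(cfg), rnc.planted_edge_indices(cfg)
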
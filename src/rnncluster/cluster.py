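"""The random neural network cluster: a random-subspace ensemble.

The ensemble is built by repeating, ``k`` times, a double random draw from
the training set — ``n`` subjects and ``m`` edge features, both uniform
without replacement — and fitting one base classifier on each draw. A new
subject is classified by majority vote over the ``k`` learners, each
voting with its own feature subset; the ensemble's accuracy on a test set
of ``N2`` subjects with ``C`` correct votes is ``C / N2``.

Randomness is organized as one master seed spawning an independent
substream per learner, so clusters are reproducible and individual
learners are independent of ``k``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.exceptions import ConvergenceWarning

from .dataset import LabeledDataset
from .learners import make_learner

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 100


class UnevaluatedClusterError(RuntimeError):
    """Per-learner accuracies were requested before :func:`evaluate_learners` ran."""


@dataclass(frozen=True)
class ClusterConfig:
    """Configuration of a random neural network cluster.

    Defaults mirror the reference protocol: 1000 learners, each trained on
    45 of the 48 training subjects and 120 of the 4005 edge features, with
    an 8:2 train/test split of the cohort.
    """

    k: int = 1000
    n_samples: int = 45
    m_features: int = 120
    train_fraction: float = 0.8
    seed: int = 0
    learner_kind: str = "mlp"
    learner_params: dict = field(default_factory=dict)
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.m_features < 1:
            raise ValueError("m_features must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class BaseLearner:
    """One trained classifier bound to its subject and feature subsets."""

    feature_indices: np.ndarray
    sample_indices: np.ndarray
    model: object
    test_accuracy: float | None = None
    converged: bool = True

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict +/-1 labels from a matrix over the full feature universe."""
        return np.asarray(self.model.predict(X[:, self.feature_indices]), dtype=int)


@dataclass
class NetworkCluster:
    """An ordered collection of ``k`` base learners plus its build config."""

    learners: list[BaseLearner]
    config: ClusterConfig
    feature_universe_size: int

    def __len__(self) -> int:
        return len(self.learners)

    @property
    def evaluated(self) -> bool:
        return all(lr.test_accuracy is not None for lr in self.learners)

    def accuracies(self) -> np.ndarray:
        if not self.evaluated:
            raise UnevaluatedClusterError(
                "per-learner accuracies not filled; run evaluate_learners first"
            )
        return np.array([lr.test_accuracy for lr in self.learners])


def split_dataset(
    D: LabeledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Randomly split a cohort into train and test sets.

    The training set gets ``floor(train_fraction * n)`` subjects (61
    subjects at 8:2 give the canonical 48/13). Splits leaving a class
    absent from the training set are redrawn a bounded number of times.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    n = D.n_subjects
    n_train = int(np.floor(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(f"split of {n} subjects at {train_fraction} leaves an empty set")
    if min(np.sum(D.labels == 1), np.sum(D.labels == -1)) < 2:
        raise ValueError("need at least 2 subjects of each class to split")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_REDRAWS):
        perm = rng.permutation(n)
        train_rows, test_rows = perm[:n_train], perm[n_train:]
        if np.unique(D.labels[train_rows]).size == 2:
            return D.subset_rows(np.sort(train_rows)), D.subset_rows(np.sort(test_rows))
    raise RuntimeError("could not draw a training set containing both classes")


def draw_subset(
    train: LabeledDataset,
    n_samples: int,
    m_features: int,
    feature_pool: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw subject rows and features, both uniform without replacement.

    ``feature_pool`` is the candidate universe — all features when building
    the initial cluster, or a ranked subset during the feature-count scan.
    """
    feature_pool = np.asarray(feature_pool, dtype=int)
    if n_samples > train.n_subjects:
        raise ValueError(f"cannot draw {n_samples} of {train.n_subjects} training subjects")
    if m_features > feature_pool.size:
        raise ValueError(f"cannot draw {m_features} of {feature_pool.size} candidate features")
    sample_idx = np.sort(rng.choice(train.n_subjects, size=n_samples, replace=False))
    feature_idx = np.sort(rng.choice(feature_pool, size=m_features, replace=False))
    return sample_idx, feature_idx


def _draw_two_class_subset(train, config, feature_pool, rng):
    for _ in range(_MAX_REDRAWS):
        sample_idx, feature_idx = draw_subset(
            train, config.n_samples, config.m_features, feature_pool, rng
        )
        if np.unique(train.labels[sample_idx]).size == 2:
            return sample_idx, feature_idx
    raise RuntimeError("could not draw a two-class subject subset")


def train_base_learner(
    train: LabeledDataset,
    sample_indices: np.ndarray,
    feature_indices: np.ndarray,
    learner_kind: str,
    learner_params: dict | None,
    random_state: int,
) -> BaseLearner:
    """Fit one base classifier on the given subject/feature subset."""
    sample_indices = np.asarray(sample_indices, dtype=int)
    feature_indices = np.asarray(feature_indices, dtype=int)
    y = train.labels[sample_indices]
    if np.unique(y).size < 2:
        raise ValueError("subject subset contains a single class; cannot train")
    model = make_learner(learner_kind, learner_params, random_state)
    X = train.features[np.ix_(sample_indices, feature_indices)]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged:
        logger.debug("base learner (%s) did not fully converge", learner_kind)
    return BaseLearner(
        feature_indices=feature_indices,
        sample_indices=sample_indices,
        model=model,
        converged=converged,
    )


def build_cluster(
    train: LabeledDataset,
    config: ClusterConfig,
    feature_pool: np.ndarray | None = None,
) -> NetworkCluster:
    """Build the ensemble: ``k`` independent learners on random subsets."""
    if feature_pool is None:
        feature_pool = np.arange(train.n_features)
    feature_pool = np.asarray(feature_pool, dtype=int)
    if config.n_samples > train.n_subjects:
        raise ValueError("config.n_samples exceeds training-set size")
    if config.m_features > feature_pool.size:
        raise ValueError("config.m_features exceeds the feature pool size")
    streams = np.random.SeedSequence(config.seed).spawn(config.k)
    learners = []
    for idx, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        try:
            if config.stratified:
                sample_idx = _stratified_draw(train.labels, config.n_samples, rng)
                feature_idx = np.sort(rng.choice(feature_pool, config.m_features, replace=False))
            else:
                sample_idx, feature_idx = _draw_two_class_subset(train, config, feature_pool, rng)
            random_state = int(rng.integers(2**31 - 1))
            learner = train_base_learner(
                train, sample_idx, feature_idx, config.learner_kind, config.learner_params, random_state
            )
        except Exception as exc:
            raise RuntimeError(f"failed to build learner {idx}: {exc}") from exc
        learners.append(learner)
    n_unconverged = sum(not lr.converged for lr in learners)
    if n_unconverged:
        logger.warning(
            "%d of %d base learners stopped before full convergence", n_unconverged, config.k
        )
    return NetworkCluster(learners=learners, config=config, feature_universe_size=train.n_features)


def _stratified_draw(labels: np.ndarray, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Draw subjects preserving the class ratio (largest-remainder rounding)."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == -1)
    n_pos = int(round(n_samples * pos.size / labels.size))
    n_pos = min(max(n_pos, 1), n_samples - 1, pos.size)
    n_neg = n_samples - n_pos
    if n_neg > neg.size:
        raise ValueError("stratified draw infeasible for requested n_samples")
    chosen = np.concatenate(
        [rng.choice(pos, n_pos, replace=False), rng.choice(neg, n_neg, replace=False)]
    )
    return np.sort(chosen)


def predict_majority(cluster: NetworkCluster, X: np.ndarray) -> np.ndarray:
    """Majority vote over all learners; exact ties resolve to +1 (HC)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != cluster.feature_universe_size:
        raise ValueError(
            f"expected {cluster.feature_universe_size} feature columns, got {X.shape}"
        )
    votes = np.zeros(X.shape[0], dtype=int)
    for learner in cluster.learners:
        votes += learner.predict(X)
    return np.where(votes >= 0, 1, -1)


def cluster_accuracy(cluster: NetworkCluster, test: LabeledDataset) -> float:
    """Fraction of test subjects whose majority-vote label matches truth (C / N2)."""
    if test.n_subjects == 0:
        raise ValueError("test set is empty")
    pred = predict_majority(cluster, test.features)
    return float(np.mean(pred == test.labels))


def evaluate_learners(cluster: NetworkCluster, eval_set: LabeledDataset) -> NetworkCluster:
    """Fill each learner's individual accuracy on ``eval_set`` (in place)."""
    if eval_set.n_subjects == 0:
        raise ValueError("evaluation set is empty")
    X = eval_set.features
    for learner in cluster.learners:
        learner.test_accuracy = float(np.mean(learner.predict(X) == eval_set.labels))
    return cluster


def out_of_bag_sets(cluster: NetworkCluster, train: LabeledDataset) -> list[np.ndarray]:
    """Per-learner training rows the learner never saw (for out-of-bag scoring)."""
    all_rows = np.arange(train.n_subjects)
    return [np.setdiff1d(all_rows, lr.sample_indices) for lr in cluster.learners]


def evaluate_learners_oob(cluster: NetworkCluster, train: LabeledDataset) -> NetworkCluster:
    """Out-of-bag alternative to :func:`evaluate_learners`.

    Scores each learner on the training subjects excluded from its draw,
    avoiding test-set leakage into downstream feature selection. Learners
    with an empty or single-class out-of-bag set get accuracy on whatever
    rows remain (empty set -> 0.0, flagged in logs).
    """
    for learner, rows in zip(cluster.learners, out_of_bag_sets(cluster, train)):
        if rows.size == 0:
            logger.warning("learner has no out-of-bag subjects; accuracy set to 0")
            learner.test_accuracy = 0.0
            continue
        pred = learner.predict(train.features[rows])
        learner.test_accuracy = float(np.mean(pred == train.labels[rows]))
    return cluster


def learner_accuracy_summary(cluster: NetworkCluster) -> dict:
    """Min/mean/max/sd of per-learner accuracies (requires evaluation)."""
    acc = cluster.accuracies()
    return {
        "min": float(acc.min()),
        "mean": float(acc.mean()),
        "max": float(acc.max()),
        "sd": float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
    }


def with_seed(config: ClusterConfig, seed: int) -> ClusterConfig:
    """A copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
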
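"""Frequency-based feature selection over the ensemble.

Learners whose individual test accuracy exceeds a threshold (0.6 by
default) are "significant"; the features they drew are pooled and each
feature is ranked by how many significant learners used it. The top-ranked
features are then re-screened by rebuilding ensembles restricted to
candidate feature-set sizes (140 to 240 in steps of 10 by default) and
picking the size with the best ensemble accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .cluster import (
    BaseLearner,
    ClusterConfig,
    NetworkCluster,
    UnevaluatedClusterError,
    build_cluster,
    cluster_accuracy,
)
from .dataset import LabeledDataset

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.6
DEFAULT_TOP_M = 240
DEFAULT_SCAN_COUNTS = tuple(range(140, 241, 10))


@dataclass(frozen=True)
class FeatureRanking:
    """Occurrence counts over the feature universe, with a deterministic order.

    ``order`` sorts features by count descending, ties broken by ascending
    feature index.
    """

    counts: np.ndarray = field(repr=False)
    order: np.ndarray = field(repr=False)

    @property
    def universe_size(self) -> int:
        return self.counts.size

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class ScanResult:
    """Ensemble accuracy per candidate feature-set size, and the winner."""

    candidate_counts: tuple[int, ...]
    accuracy_per_count: tuple[float, ...]
    optimal_count: int


def select_significant_learners(
    cluster: NetworkCluster, threshold: float = DEFAULT_THRESHOLD
) -> list[BaseLearner]:
    """Learners with accuracy strictly greater than ``threshold``, in order."""
    if not cluster.evaluated:
        raise UnevaluatedClusterError("evaluate learners before selecting significant ones")
    return [lr for lr in cluster.learners if lr.test_accuracy > threshold]


def feature_frequency(significant: list[BaseLearner], universe_size: int) -> FeatureRanking:
    """Count, per feature, the significant learners that drew it."""
    universe_size = int(universe_size)
    if significant:
        all_idx = np.concatenate([lr.feature_indices for lr in significant])
        if all_idx.size and all_idx.max() >= universe_size:
            raise ValueError("feature index exceeds declared universe size")
        counts = np.bincount(all_idx, minlength=universe_size)
    else:
        counts = np.zeros(universe_size, dtype=int)
    order = np.lexsort((np.arange(universe_size), -counts))
    return FeatureRanking(counts=counts, order=order)


def top_features(ranking: FeatureRanking, m: int) -> np.ndarray:
    """The first ``m`` features of the ranking (count-desc, index-asc ties)."""
    if m < 0 or m > ranking.universe_size:
        raise ValueError(f"m={m} out of range for a {ranking.universe_size}-feature universe")
    return ranking.order[:m].copy()


def scan_feature_counts(
    train: LabeledDataset,
    test: LabeledDataset,
    ranking: FeatureRanking,
    candidate_counts: tuple[int, ...] = DEFAULT_SCAN_COUNTS,
    config: ClusterConfig | None = None,
) -> ScanResult:
    """Rebuild the ensemble for each candidate feature-set size and score it.

    Each candidate ``c`` restricts the per-learner feature draw to the top
    ``c`` ranked features; learners still draw ``config.m_features`` each.
    All candidates reuse the same master seed, so they differ only by
    feature pool. The optimal count is the accuracy argmax, ties going to
    the smallest (most parsimonious) count. Candidates exceeding the number
    of features that ever occurred in a significant learner are capped.
    """
    config = config or ClusterConfig()
    candidates = sorted(int(c) for c in candidate_counts)
    if not candidates:
        raise ValueError("candidate_counts is empty")
    available = ranking.n_nonzero
    if candidates[-1] > available:
        logger.warning(
            "capping scan candidates at %d features with nonzero counts", available
        )
        candidates = sorted({min(c, available) for c in candidates})
    if config.m_features > candidates[0]:
        raise ValueError(
            f"m_features={config.m_features} exceeds smallest candidate count {candidates[0]}"
        )
    accuracies = []
    for c in candidates:
        pool = top_features(ranking, c)
        cluster = build_cluster(train, config, feature_pool=pool)
        accuracies.append(cluster_accuracy(cluster, test))
    best = int(np.argmax(accuracies))  # first max -> smallest count on ties
    return ScanResult(
        candidate_counts=tuple(candidates),
        accuracy_per_count=tuple(accuracies),
        optimal_count=candidates[best],
    )


def scan_config(config: ClusterConfig, scan_k: int | None) -> ClusterConfig:
    """Config used inside the scan; ``scan_k`` overrides ``k`` for desk-scale runs."""
    if scan_k is None:
        return config
    return replace(config, k=int(scan_k))
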
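"""End-to-end orchestration: split, ensemble, selection, scan, reports.

The full procedure mirrors the reference protocol: split the cohort 8:2,
build a k-learner ensemble on the training set, score every learner on
the held-out set, keep learners above the significance threshold, rank
features by occurrence frequency, retain the top 240, scan candidate
feature-set sizes 140..240 (step 10) by rebuilding ensembles restricted to
each candidate pool, and return the feature set at the best-scoring size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .cluster import (
    ClusterConfig,
    NetworkCluster,
    build_cluster,
    cluster_accuracy,
    evaluate_learners,
    evaluate_learners_oob,
    learner_accuracy_summary,
    split_dataset,
)
from .dataset import LabeledDataset
from .edges import index_to_edge
from .selection import (
    DEFAULT_SCAN_COUNTS,
    DEFAULT_THRESHOLD,
    DEFAULT_TOP_M,
    FeatureRanking,
    ScanResult,
    feature_frequency,
    scan_config,
    scan_feature_counts,
    select_significant_learners,
    top_features,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the full procedure deterministically."""

    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    threshold: float = DEFAULT_THRESHOLD
    top_m: int = DEFAULT_TOP_M
    scan_counts: tuple[int, ...] = DEFAULT_SCAN_COUNTS
    scan_k: int | None = None
    oob_evaluation: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scan_counts"] = list(self.scan_counts)
        return d


@dataclass
class PipelineResult:
    """Outputs of one full run."""

    train: LabeledDataset
    test: LabeledDataset
    cluster: NetworkCluster
    cluster_accuracy: float
    n_significant: int
    ranking: FeatureRanking
    scan: ScanResult
    selected_features: np.ndarray
    config: PipelineConfig

    def report(self) -> dict:
        """Summary suitable for JSON serialization."""
        return {
            "n_subjects": self.train.n_subjects + self.test.n_subjects,
            "n_train": self.train.n_subjects,
            "n_test": self.test.n_subjects,
            "n_features": self.train.n_features,
            "cluster_accuracy": self.cluster_accuracy,
            "learner_accuracy": learner_accuracy_summary(self.cluster),
            "n_significant_learners": self.n_significant,
            "scan": {
                "counts": list(self.scan.candidate_counts),
                "accuracy": list(self.scan.accuracy_per_count),
                "optimal_count": self.scan.optimal_count,
            },
            "n_selected_features": int(self.selected_features.size),
            "config": self.config.to_dict(),
        }


def run_full_pipeline(D: LabeledDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Run split -> ensemble -> significance -> ranking -> scan -> selection."""
    config = config or PipelineConfig()
    cc = config.cluster
    try:
        train, test = split_dataset(D, cc.train_fraction, cc.seed)
    except Exception as exc:
        raise PipelineError(f"split: {exc}") from exc
    try:
        cluster = build_cluster(train, cc)
    except Exception as exc:
        raise PipelineError(f"build_cluster: {exc}") from exc
    try:
        if config.oob_evaluation:
            evaluate_learners_oob(cluster, train)
        else:
            evaluate_learners(cluster, test)
        acc = cluster_accuracy(cluster, test)
    except Exception as exc:
        raise PipelineError(f"evaluate: {exc}") from exc
    significant = select_significant_learners(cluster, config.threshold)
    if not significant:
        raise PipelineError(
            "selection: no learner exceeded the significance threshold "
            f"{config.threshold}; lower --threshold or increase k"
        )
    ranking = feature_frequency(significant, D.n_features)
    # conservation check: every significant learner contributes exactly m features
    assert ranking.counts.sum() == len(significant) * cc.m_features
    top_m = min(config.top_m, ranking.n_nonzero)
    try:
        scan = scan_feature_counts(
            train,
            test,
            ranking,
            tuple(c for c in config.scan_counts if c <= top_m) or (top_m,),
            scan_config(cc, config.scan_k),
        )
    except Exception as exc:
        raise PipelineError(f"scan: {exc}") from exc
    selected = top_features(ranking, scan.optimal_count)
    return PipelineResult(
        train=train,
        test=test,
        cluster=cluster,
        cluster_accuracy=acc,
        n_significant=len(significant),
        ranking=ranking,
        scan=scan,
        selected_features=selected,
        config=config,
    )


# ---------------------------------------------------------------- exports


def ranking_frame(ranking: FeatureRanking, atlas: RegionAtlas | None = None) -> pd.DataFrame:
    """Ranked feature table with region annotations when an atlas is given."""
    order = ranking.order
    rows = {
        "feature_index": order,
        "count": ranking.counts[order],
        "rank": np.arange(1, order.size + 1),
    }
    if atlas is not None:
        pairs = [index_to_edge(int(f), atlas.region_count) for f in order]
        rows["region_i"] = [p[0] for p in pairs]
        rows["region_j"] = [p[1] for p in pairs]
        rows["abbrev_i"] = [atlas.abbreviations[p[0]] for p in pairs]
        rows["abbrev_j"] = [atlas.abbreviations[p[1]] for p in pairs]
        cols = ["feature_index", "region_i", "region_j", "abbrev_i", "abbrev_j", "count", "rank"]
        return pd.DataFrame(rows)[cols]
    return pd.DataFrame(rows)


def write_ranking_csv(ranking: FeatureRanking, path, atlas: RegionAtlas | None = None,
                      limit: int | None = None) -> None:
    df = ranking_frame(ranking, atlas)
    if limit is not None:
        df = df.head(limit)
    df.to_csv(path, index=False)


def write_scan_csv(scan: ScanResult, path) -> None:
    pd.DataFrame(
        {"count": scan.candidate_counts, "accuracy": scan.accuracy_per_count}
    ).to_csv(path, index=False, float_format="%.10g")


def plot_scan(scan: ScanResult, path) -> None:
    """Accuracy-versus-feature-count curve (one line, optimal point marked)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(scan.candidate_counts, scan.accuracy_per_count, "o-")
    i = scan.candidate_counts.index(scan.optimal_count)
    ax.plot([scan.optimal_count], [scan.accuracy_per_count[i]], "r*", markersize=12)
    ax.set_xlabel("number of significant features")
    ax.set_ylabel("ensemble accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report_json(result: PipelineResult, path) -> None:
    Path(path).write_text(json.dumps(result.report(), indent=2, sort_keys=True) + "\n")
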
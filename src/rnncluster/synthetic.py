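"""Synthetic two-group cohorts with planted connectivity differences.

Real resting-state cohorts cannot ship with the package, so every pipeline
stage is exercised on simulated data: two groups of multivariate-normal
ROI time series whose population correlation differs, by ``delta``, on a
chosen set of "planted" edges. Group sizes default to the motivating
cohort (36 controls, 25 patients). The planted edges are the ground truth
against which feature selection is judged.

Two generators are provided: :func:`simulate_cohort` draws full T x R time
series (so Pearson estimation noise is realistic), and
:func:`simulate_feature_matrix` emits FC-like features directly for fast
unit tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .connectivity import RoiTimeSeries
from .dataset import LabeledDataset
from .edges import edge_feature_names, edge_to_index, n_edges, vector_to_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the simulated cohort.

    ``planted_edges`` may be an integer (that many edges drawn at random,
    deterministically from ``seed``) or an explicit list of ``(i, j)``
    region pairs. ``base_r`` is the background inter-regional correlation;
    the patient group (-1) gets ``base_r + delta`` on planted edges.
    ``noise_sd`` is the observation noise used by the direct feature-matrix
    generator; it approximates the sampling scatter of a Pearson estimate
    at roughly 100 timepoints.
    """

    R: int = 90
    T: int = 130
    n_group_pos: int = 36
    n_group_neg: int = 25
    planted_edges: int | tuple = 20
    base_r: float = 0.1
    delta: float = 0.4
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.R < 2 or self.T < 3:
            raise ValueError("need R >= 2 regions and T >= 3 timepoints")
        if self.n_group_pos < 1 or self.n_group_neg < 1:
            raise ValueError("both groups need at least one subject")
        if not (0.0 <= self.base_r < 1.0) or abs(self.base_r + self.delta) >= 1.0:
            raise ValueError("base_r and base_r + delta must lie strictly inside (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_subjects(self) -> int:
        return self.n_group_pos + self.n_group_neg


def planted_edge_indices(config: SyntheticConfig) -> np.ndarray:
    """Flat indices of the planted edges, resolved deterministically."""
    total = n_edges(config.R)
    if isinstance(config.planted_edges, int):
        count = config.planted_edges
        if not (0 <= count <= total):
            raise ValueError(f"cannot plant {count} of {total} edges")
        ss = np.random.SeedSequence([config.seed, 0x9E3779B9])  # dedicated stream
        rng = np.random.default_rng(ss)
        return np.sort(rng.choice(total, size=count, replace=False))
    idx = [edge_to_index(min(i, j), max(i, j), config.R) for i, j in config.planted_edges]
    idx = np.sort(np.asarray(idx, dtype=int))
    if np.unique(idx).size != idx.size:
        raise ValueError("planted edge list contains duplicates")
    return idx


def make_group_correlation(config: SyntheticConfig, group: int) -> np.ndarray:
    """Population R x R correlation matrix for one group.

    Background entries are ``base_r``; planted entries are ``base_r +
    delta`` for the patient group (-1). If the raw construction is not
    positive semi-definite it is repaired by eigenvalue clipping and
    re-normalized to unit diagonal; a repair that moves any planted entry
    by more than ``delta / 4`` is a configuration error (the requested
    signal does not admit a valid correlation structure).
    """
    if group not in (-1, 1):
        raise ValueError("group must be +1 or -1")
    vec = np.full(n_edges(config.R), config.base_r)
    planted = planted_edge_indices(config)
    if group == -1:
        vec[planted] = config.base_r + config.delta
    corr = vector_to_matrix(vec, config.R, diagonal=1.0)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < -1e-10:
        corr = _psd_repair(corr)
        if planted.size:
            rows, cols = zip(*[_edge_pair(f, config.R) for f in planted])
            target = config.base_r + (config.delta if group == -1 else 0.0)
            shift = np.abs(corr[list(rows), list(cols)] - target).max()
            logger.info("PSD repair moved planted correlations by up to %.2g", shift)
            if shift > abs(config.delta) / 4:
                raise ValueError(
                    "planted signal too strong for a valid correlation matrix "
                    f"(PSD repair shifted entries by {shift:.3g})"
                )
    return corr


def _edge_pair(flat: int, r: int) -> tuple[int, int]:
    from .edges import index_to_edge

    return index_to_edge(int(flat), r)


def _psd_repair(corr: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, floor, None)
    repaired = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def simulate_cohort(config: SyntheticConfig) -> list[RoiTimeSeries]:
    """Draw each subject's T x R series from the group's correlation model.

    Timepoints are i.i.d. multivariate normal (no temporal autocorrelation);
    controls (+1, ids ``HC..``) precede patients (-1, ids ``AD..``).
    """
    chol = {g: np.linalg.cholesky(make_group_correlation(config, g)) for g in (1, -1)}
    ss = np.random.SeedSequence([config.seed, 0x51ED2701])
    streams = ss.spawn(config.n_subjects)
    cohort = []
    labels = [1] * config.n_group_pos + [-1] * config.n_group_neg
    counters = {1: 0, -1: 0}
    for label, stream in zip(labels, streams):
        counters[label] += 1
        prefix = "HC" if label == 1 else "AD"
        rng = np.random.default_rng(stream)
        z = rng.standard_normal((config.T, config.R))
        cohort.append(
            RoiTimeSeries(
                subject_id=f"{prefix}{counters[label]:03d}",
                values=z @ chol[label].T,
                label=label,
            )
        )
    return cohort


def simulate_feature_matrix(config: SyntheticConfig) -> LabeledDataset:
    """Direct FC-like feature generator (no time series), for fast tests.

    Every feature is ``base_r`` plus Gaussian noise of sd ``noise_sd``;
    planted features additionally carry ``delta`` for patients. Values are
    clipped to the correlation range [-1, 1].
    """
    planted = planted_edge_indices(config)
    total = n_edges(config.R)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFEA70000]))
    labels = np.array([1] * config.n_group_pos + [-1] * config.n_group_neg)
    X = config.base_r + config.noise_sd * rng.standard_normal((config.n_subjects, total))
    X[np.ix_(labels == -1, planted)] += config.delta
    X = np.clip(X, -1.0, 1.0)
    ids = [f"HC{i + 1:03d}" for i in range(config.n_group_pos)] + [
        f"AD{i + 1:03d}" for i in range(config.n_group_neg)
    ]
    return LabeledDataset(
        features=X,
        labels=labels,
        subject_ids=tuple(ids),
        feature_names=tuple(edge_feature_names(config.R)),
    )
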
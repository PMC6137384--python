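"""Pearson functional connectivity from ROI time series.

Functional connectivity (FC) between two brain regions is the Pearson
correlation of their mean-signal time series. For an ``R``-region atlas
each subject yields ``R (R - 1) / 2`` FC values — 4005 for the 90-region
AAL parcellation — stored in the flat edge order of :mod:`rnncluster.edges`.
The correlations are raw ``r`` values; no Fisher z transform is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .dataset import LabeledDataset
from .edges import edge_endpoints, edge_feature_names, n_edges


class DegenerateTimeSeriesError(ValueError):
    """A region's time series has zero variance, so its correlations are undefined."""


@dataclass
class RoiTimeSeries:
    """One subject's region-averaged time series (T timepoints x R regions)."""

    subject_id: str
    values: np.ndarray = field(repr=False)
    label: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be 2-D (timepoints x regions)")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 timepoints to estimate correlations")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"subject {self.subject_id}: time series contains non-finite values")
        if self.label not in (-1, 1):
            raise ValueError("label must be +1 (HC) or -1 (AD)")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def compute_fc(ts: RoiTimeSeries, atlas: RegionAtlas) -> np.ndarray:
    """Flat vector of pairwise Pearson correlations between region time series.

    Entry ``edge_to_index(i, j)`` is the correlation of regions ``i`` and
    ``j``. A constant region trace is an error (its correlation is
    undefined), reported with the offending region's abbreviation.
    """
    if ts.n_regions != atlas.region_count:
        raise ValueError(
            f"subject {ts.subject_id}: {ts.n_regions} regions but atlas has {atlas.region_count}"
        )
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(atlas.abbreviations[i] for i in dead[:5])
        raise DegenerateTimeSeriesError(
            f"subject {ts.subject_id}: constant time series in region(s) {names}"
        )
    corr = np.corrcoef(ts.values, rowvar=False)
    rows, cols = edge_endpoints(atlas.region_count)
    return np.clip(corr[rows, cols], -1.0, 1.0)


def build_feature_matrix(cohort: list[RoiTimeSeries], atlas: RegionAtlas) -> LabeledDataset:
    """Stack per-subject FC vectors into a labeled subject x edge matrix."""
    if not cohort:
        raise ValueError("cohort is empty")
    counts = {ts.n_regions for ts in cohort}
    if counts != {atlas.region_count}:
        raise ValueError(f"mixed or mismatched region counts {sorted(counts)} vs atlas {atlas.region_count}")
    feats = np.vstack([compute_fc(ts, atlas) for ts in cohort])
    return LabeledDataset(
        features=feats,
        labels=np.array([ts.label for ts in cohort]),
        subject_ids=tuple(ts.subject_id for ts in cohort),
        feature_names=tuple(edge_feature_names(atlas.region_count)),
    )


def read_timeseries_csv(path, subject_id: str, label: int) -> RoiTimeSeries:
    """Load one subject's T x R time-series table (optional header row)."""
    first = pd.read_csv(path, nrows=1, header=None)
    has_header = not np.issubdtype(first.dtypes.iloc[0], np.number)
    df = pd.read_csv(path, header=0 if has_header else None)
    return RoiTimeSeries(subject_id=subject_id, values=df.to_numpy(dtype=float), label=label)


def read_manifest(path) -> list[RoiTimeSeries]:
    """Load a cohort from a manifest CSV with columns subject_id, path, label.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "path", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    cohort = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        cohort.append(read_timeseries_csv(p, str(row.subject_id), int(row.label)))
    return cohort


def write_cohort(cohort: list[RoiTimeSeries], outdir) -> Path:
    """Write per-subject time-series CSVs plus a manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in cohort:
        fname = f"ts_{ts.subject_id}.csv"
        pd.DataFrame(ts.values).to_csv(outdir / fname, index=False, header=False, float_format="%.10g")
        rows.append({"subject_id": ts.subject_id, "path": fname, "label": ts.label})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
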
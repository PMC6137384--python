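"""Labeled subject-by-feature datasets and their delimited-text round trip."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabeledDataset:
    """A subject x feature matrix with +/-1 class labels.

    Labels follow the convention +1 = healthy control (HC), -1 = patient
    (AD in the motivating application).
    """

    features: np.ndarray = field(repr=False)
    labels: np.ndarray
    subject_ids: tuple[str, ...]
    feature_names: tuple[str, ...] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (subjects x features)")
        n = self.features.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("label count must equal subject count")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids count must equal subject count")
        if self.feature_names is not None and len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must equal feature count")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset_rows(self, rows: np.ndarray) -> "LabeledDataset":
        rows = np.asarray(rows, dtype=int)
        return LabeledDataset(
            features=self.features[rows],
            labels=self.labels[rows],
            subject_ids=tuple(self.subject_ids[i] for i in rows),
            feature_names=self.feature_names,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"f{i}" for i in range(self.n_features)]
        )
        df = pd.DataFrame(self.features, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", list(self.subject_ids))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        if "subject_id" not in df.columns or "label" not in df.columns:
            raise ValueError("dataset table needs 'subject_id' and 'label' columns")
        feat_cols = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            features=df[feat_cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            subject_ids=tuple(df["subject_id"].astype(str)),
            feature_names=tuple(feat_cols),
        )

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        return cls.from_frame(pd.read_csv(path))
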
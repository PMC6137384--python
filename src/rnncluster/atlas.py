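"""Region atlas metadata (index, name, abbreviation, MNI coordinates)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ATLAS_COLUMNS = ["index", "name", "abbreviation", "x", "y", "z"]


@dataclass(frozen=True)
class RegionAtlas:
    """A brain parcellation: one record per region.

    Parameters
    ----------
    names, abbreviations : sequences of str, one per region
    mni : (R, 3) array of MNI coordinates in millimetres
    """

    names: tuple[str, ...]
    abbreviations: tuple[str, ...]
    mni: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mni = np.asarray(self.mni, dtype=float)
        object.__setattr__(self, "mni", mni)
        r = len(self.names)
        if len(self.abbreviations) != r:
            raise ValueError("names and abbreviations must have equal length")
        if mni.shape != (r, 3):
            raise ValueError(f"mni must have shape ({r}, 3), got {mni.shape}")
        if len(set(self.abbreviations)) != r:
            raise ValueError("region abbreviations must be unique")

    @property
    def region_count(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.region_count),
                "name": list(self.names),
                "abbreviation": list(self.abbreviations),
                "x": self.mni[:, 0],
                "y": self.mni[:, 1],
                "z": self.mni[:, 2],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionAtlas":
        missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        df = df.sort_values("index").reset_index(drop=True)
        idx = df["index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(df))):
            raise ValueError("atlas indices must be 0..R-1 with no gaps or duplicates")
        return cls(
            names=tuple(df["name"].astype(str)),
            abbreviations=tuple(df["abbreviation"].astype(str)),
            mni=df[["x", "y", "z"]].to_numpy(dtype=float),
        )

    @classmethod
    def from_tsv(cls, path) -> "RegionAtlas":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def synthetic_atlas(region_count: int = 90) -> RegionAtlas:
    """A synthetic placeholder atlas with generated names and coordinates.

    Stands in for a real parcellation (e.g. AAL-90) when only the region
    count matters: regions are named ``region_001 ...`` and placed on a
    deterministic spiral on a 70 mm sphere so that exported node files are
    viewable. Coordinates carry no anatomical meaning.
    """
    r = int(region_count)
    if r < 1:
        raise ValueError("region_count must be positive")
    k = np.arange(r)
    # Fibonacci sphere: roughly uniform, fully deterministic
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zfrac = 1.0 - 2.0 * (k + 0.5) / r
    rad = np.sqrt(np.clip(1.0 - zfrac**2, 0.0, 1.0))
    theta = golden * k
    mni = 70.0 * np.column_stack([rad * np.cos(theta), rad * np.sin(theta), zfrac])
    width = max(3, len(str(r)))
    names = tuple(f"region_{i + 1:0{width}d}" for i in range(r))
    abbrevs = tuple(f"R{i + 1:0{width}d}" for i in range(r))
    return RegionAtlas(names=names, abbreviations=abbrevs, mni=np.round(mni, 1))
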
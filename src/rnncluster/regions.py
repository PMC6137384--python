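"""Map selected edge features to brain regions and export viewer files.

Each selected edge touches two regions; a region's weight is the number of
selected edges incident to it, so the weights always sum to twice the
number of selected edges. A region no selected edge touches has weight 0.
Higher weight is read as a stronger involvement of that region in the
group difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .edges import index_to_edge, n_edges, vector_to_matrix


@dataclass(frozen=True)
class RegionWeightTable:
    """Per-region incidence weights for a set of selected edges."""

    region_indices: np.ndarray = field(repr=False)
    abbreviations: tuple[str, ...]
    mni: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.region_indices,
                "abbreviation": list(self.abbreviations),
                "x": self.mni[:, 0],
                "y": self.mni[:, 1],
                "z": self.mni[:, 2],
                "weight": self.weights,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def selected_edge_pairs(selected_features: np.ndarray, region_count: int) -> list[tuple[int, int]]:
    """Decode flat edge indices to ``(i, j)`` region pairs, validating them."""
    selected = np.asarray(selected_features, dtype=int)
    total = n_edges(region_count)
    if selected.size and (selected.min() < 0 or selected.max() >= total):
        raise ValueError(f"selected edge index out of range 0..{total - 1}")
    if np.unique(selected).size != selected.size:
        raise ValueError("duplicate edge indices in selection; selections must be sets")
    return [index_to_edge(int(f), region_count) for f in selected]


def region_weights(selected_features: np.ndarray, atlas: RegionAtlas) -> RegionWeightTable:
    """Count, per region, the selected edges incident to it."""
    r = atlas.region_count
    pairs = selected_edge_pairs(selected_features, r)
    endpoints = np.array([p for pair in pairs for p in pair], dtype=int)
    weights = np.bincount(endpoints, minlength=r) if endpoints.size else np.zeros(r, dtype=int)
    return RegionWeightTable(
        region_indices=np.arange(r),
        abbreviations=atlas.abbreviations,
        mni=atlas.mni,
        weights=weights,
    )


def filter_regions(table: RegionWeightTable, min_weight: int) -> RegionWeightTable:
    """Regions with weight strictly above ``min_weight``, heaviest first.

    Ties are ordered by abbreviation so output is fully deterministic.
    """
    if min_weight < 0:
        raise ValueError("min_weight must be >= 0")
    keep = np.flatnonzero(table.weights > min_weight)
    keep = sorted(keep, key=lambda i: (-table.weights[i], table.abbreviations[i]))
    keep = np.asarray(keep, dtype=int)
    return RegionWeightTable(
        region_indices=table.region_indices[keep],
        abbreviations=tuple(table.abbreviations[i] for i in keep),
        mni=table.mni[keep],
        weights=table.weights[keep],
    )


def export_brainnet(
    table: RegionWeightTable,
    selected_features: np.ndarray,
    atlas: RegionAtlas,
    node_path,
    edge_path,
) -> tuple[Path, Path]:
    """Write BrainNet Viewer ``.node`` and ``.edge`` text files.

    ``.node``: one region per row, six whitespace-separated columns — MNI
    x, y, z, color, size, label. Color and size are both set to the
    region's weight. ``.edge``: the R x R symmetric 0/1 adjacency matrix
    of the selected edges.
    """
    node_path, edge_path = Path(node_path), Path(edge_path)
    r = atlas.region_count
    if table.weights.size != r:
        raise ValueError("weight table must cover every atlas region; filter after export")
    lines = []
    for i in range(r):
        x, y, z = table.mni[i]
        w = int(table.weights[i])
        lines.append(f"{x:g}\t{y:g}\t{z:g}\t{w}\t{w}\t{table.abbreviations[i]}")
    try:
        node_path.write_text("\n".join(lines) + "\n")
        vec = np.zeros(n_edges(r), dtype=int)
        vec[np.asarray(selected_features, dtype=int)] = 1
        adj = vector_to_matrix(vec, r, diagonal=0.0).astype(int)
        np.savetxt(edge_path, adj, fmt="%d", delimiter="\t")
    except OSError as exc:
        raise OSError(f"failed writing BrainNet files at {exc.filename}: {exc}") from exc
    return node_path, edge_path


def read_brainnet_edges(edge_path, region_count: int) -> np.ndarray:
    """Recover the flat selected-edge indices from a written ``.edge`` file."""
    adj = np.loadtxt(edge_path)
    if adj.shape != (region_count, region_count):
        raise ValueError(f"expected a {region_count} x {region_count} matrix")
    from .edges import matrix_to_vector

    return np.flatnonzero(matrix_to_vector(adj) != 0)
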
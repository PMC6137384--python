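"""Edge indexing for functional-connectivity feature vectors.

A connectome over ``R`` regions has ``R * (R - 1) / 2`` unordered region
pairs ("edges"). Feature vectors store one value per edge, in row-major
order over the strict upper triangle of the ``R x R`` matrix: ``(0, 1),
(0, 2), ..., (0, R-1), (1, 2), ...``. All indices are 0-based.
"""

from __future__ import annotations

import numpy as np


def n_edges(region_count: int) -> int:
    """Number of unordered region pairs for a ``region_count``-region atlas.

    For the 90-region AAL parcellation this is 4005.
    """
    if int(region_count) != region_count or region_count < 1:
        raise ValueError(f"region_count must be a positive integer, got {region_count!r}")
    region_count = int(region_count)
    return region_count * (region_count - 1) // 2


def edge_to_index(i: int, j: int, region_count: int) -> int:
    """Flat feature index of the edge between regions ``i < j``."""
    r = int(region_count)
    if not (0 <= i < j < r):
        raise ValueError(f"require 0 <= i < j < R, got i={i}, j={j}, R={r}")
    # row-major strict upper triangle: full rows above i, then offset in row i
    return i * r - i * (i + 1) // 2 + (j - i - 1)


def index_to_edge(index: int, region_count: int) -> tuple[int, int]:
    """Inverse of :func:`edge_to_index`."""
    r = int(region_count)
    total = n_edges(r)
    if not (0 <= index < total):
        raise ValueError(f"edge index {index} out of range for R={r} ({total} edges)")
    # solve for the row i such that its cumulative edge count covers `index`
    i = int((2 * r - 1 - np.sqrt((2 * r - 1) ** 2 - 8 * index)) // 2)
    while edge_to_index(i, i + 1, r) > index:  # guard float rounding
        i -= 1
    while i + 1 < r - 1 and edge_to_index(i + 1, i + 2, r) <= index:
        i += 1
    j = index - edge_to_index(i, i + 1, r) + i + 1
    return i, j


def edge_endpoints(region_count: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays ``(rows, cols)`` giving the region pair of every flat index."""
    return np.triu_indices(int(region_count), k=1)


def matrix_to_vector(mat: np.ndarray) -> np.ndarray:
    """Flatten a symmetric ``R x R`` matrix to the edge-ordered vector."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    rows, cols = edge_endpoints(mat.shape[0])
    return mat[rows, cols].copy()


def vector_to_matrix(vec: np.ndarray, region_count: int, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric ``R x R`` matrix from an edge-ordered vector."""
    vec = np.asarray(vec)
    r = int(region_count)
    if vec.shape != (n_edges(r),):
        raise ValueError(f"expected vector of length {n_edges(r)} for R={r}, got shape {vec.shape}")
    mat = np.full((r, r), float(diagonal))
    rows, cols = edge_endpoints(r)
    mat[rows, cols] = vec
    mat[cols, rows] = vec
    return mat


def edge_feature_names(region_count: int) -> list[str]:
    """Column names ``FC_i_j`` for the flat feature vector."""
    rows, cols = edge_endpoints(region_count)
    return [f"FC_{i}_{j}" for i, j in zip(rows.tolist(), cols.tolist())]
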
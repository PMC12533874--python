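"""KNN spot graphs and their self-loop symmetric normalisation.

Two graphs feed the multi-view encoder: a spatial graph over spot coordinates
(Euclidean KNN; the field's default is k=25 for 10x Visium and k=50 for
Stereo-seq) and a feature graph over spot expression profiles (cosine KNN).
Directed KNN edges are symmetrised by union, and graph convolutions use the
self-loop symmetric normalisation D̃^{-1/2}(A+I)D̃^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import ConfigError, DataError

__all__ = [
    "SpotGraph",
    "build_knn_graph",
    "normalize_adjacency",
    "default_k",
    "PLATFORM_K",
]

# spatial-graph neighbour counts by platform
PLATFORM_K = {"visium": 25, "stereo-seq": 50}


def default_k(platform: str) -> int:
    """Spatial-graph neighbour count for a named platform."""
    try:
        return PLATFORM_K[platform.lower().replace("_", "-")]
    except KeyError:
        raise ConfigError(f"platform: no default k for {platform!r}") from None


@dataclass
class SpotGraph:
    """A binary adjacency over spots plus its normalised operator."""

    adjacency: sp.csr_matrix
    k: int
    metric: str
    normalized: sp.csr_matrix | None = None

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]


def _knn_edges(points: np.ndarray, k: int, metric: str) -> np.ndarray:
    """Directed k-nearest-neighbour lists, ties broken by (distance, index).

    Brute force in row chunks; exact and fully deterministic, which matters
    more than speed at the spot counts this package targets.
    """
    n = points.shape[0]
    if metric == "cosine":
        norms = np.linalg.norm(points, axis=1)
        zero = np.flatnonzero(norms == 0)
        if zero.size:
            raise DataError(
                f"cosine metric undefined for all-zero expression profile of "
                f"spot index {int(zero[0])}"
            )
        unit = points / norms[:, None]
    neighbors = np.empty((n, k), dtype=np.int64)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        if metric == "euclidean":
            d = np.linalg.norm(points[start:stop, None, :] - points[None, :, :], axis=2)
        elif metric == "cosine":
            d = 1.0 - unit[start:stop] @ unit.T
        else:
            raise ConfigError(f"metric: unknown metric {metric!r}")
        rows = np.arange(start, stop)
        d[np.arange(stop - start), rows] = np.inf  # exclude self
        for i, row in enumerate(d):
            order = np.lexsort((np.arange(n), row))
            neighbors[start + i] = order[:k]
    return neighbors


def build_knn_graph(points: np.ndarray, k: int, metric: str = "euclidean") -> SpotGraph:
    """Union-symmetrised KNN graph over rows of ``points``.

    Each spot selects its k nearest others (self excluded); an undirected edge
    is kept if either endpoint selected the other.  The normalised operator is
    attached via :func:`normalize_adjacency`.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise DataError("points must be a 2-D array")
    if not np.all(np.isfinite(points)):
        raise DataError("points contain non-finite values")
    n = points.shape[0]
    if k < 1 or k >= n:
        raise ConfigError(f"k: need 1 <= k < n_spots, got k={k} with n={n}")
    nbrs = _knn_edges(points, k, metric)
    rows = np.repeat(np.arange(n), k)
    a = sp.coo_matrix(
        (np.ones(n * k), (rows, nbrs.ravel())), shape=(n, n)
    ).tocsr()
    a = ((a + a.T) > 0).astype(np.float64)  # union symmetrisation
    a.setdiag(0)
    a.eliminate_zeros()
    g = SpotGraph(adjacency=a.tocsr(), k=k, metric=metric)
    return normalize_adjacency(g)


def normalize_adjacency(g: SpotGraph) -> SpotGraph:
    """Attach D̃^{-1/2}(A+I)D̃^{-1/2} with D̃ the degree matrix of A+I."""
    a = g.adjacency.tocsr()
    if (abs(a - a.T)).nnz != 0:
        raise DataError("adjacency must be symmetric")
    if a.diagonal().any():
        raise DataError("adjacency must have zero diagonal")
    if a.nnz and not np.all(a.data == 1.0):
        raise DataError("adjacency must be binary")
    a_tilde = (a + sp.identity(a.shape[0], format="csr")).tocsr()
    deg = np.ravel(a_tilde.sum(axis=1))
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    g.normalized = (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr()
    return g


def export_graph(g: SpotGraph, out_prefix: str | Path) -> None:
    """Write the adjacency as MatrixMarket plus an edge-list TSV."""
    import scipy.io as sio

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(out_prefix) + ".mtx", g.adjacency)
    coo = sp.triu(g.adjacency).tocoo()
    with open(str(out_prefix) + "_edges.tsv", "w") as fh:
        fh.write("source\ttarget\n")
        for i, j in zip(coo.row, coo.col):
            fh.write(f"{i}\t{j}\n")
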
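"""Per-sample spatial kNN graph: construction, edge weighting, pruning.

Edges connect each unit to its k spatial nearest neighbours (Euclidean
distance on the tissue coordinates); weights measure expression similarity
in PC space, either as the Pearson correlation of the two endpoint rows or
as a shared-nearest-neighbour overlap for sparse data. The smoothed variant
replaces each endpoint by the average of its spatial neighbourhood
(excluding neighbours shared with the other endpoint) before correlating,
which damps unit-level noise while keeping genuine tissue boundaries sharp.
Edges below a threshold (default 0.6) are pruned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .reduction import ReducedMatrix

__all__ = [
    "SpatialGraph",
    "build_spatial_knn",
    "edge_weight_pearson",
    "edge_weight_snn",
    "compute_edge_weights",
    "smoothed_edge_weights",
    "prune_edges",
    "spatial_knn_indices",
]


@dataclass
class SpatialGraph:
    """Undirected weighted graph over the units of one sample.

    ``edges`` is an (E, 2) int array with u < v and no self-loops;
    ``weights`` aligns with edges (None before weighting). ``coords`` is
    kept so neighbourhood smoothing can query spatial proximity.
    """

    sample_id: str
    n_nodes: int
    edges: np.ndarray
    coords: np.ndarray
    k: int
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("self-loop in edge set")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbor_lists(self):
        """Adjacency as a list of sorted int arrays."""
        adj = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return [np.array(sorted(a), dtype=int) for a in adj]


def spatial_knn_indices(coords, k: int) -> np.ndarray:
    """(n, k) array of each point's k nearest neighbours, self excluded.

    Ties in distance break deterministically by lower point index.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k >= n:
        raise ValueError(f"k={k} must be < n_units={n}")
    tree = cKDTree(coords)
    # over-query to resolve distance ties reproducibly
    m = min(n, k + 16)
    dist, idx = tree.query(coords, k=m)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        d, j = dist[i], idx[i]
        mask = j != i
        d, j = d[mask], j[mask]
        order = np.lexsort((j, np.round(d, 9)))
        out[i] = j[order[:k]]
    return out


def build_spatial_knn(coords, k: int, sample_id: str = "") -> SpatialGraph:
    """kNN graph on spatial coordinates, symmetrized by union.

    An undirected edge (u, v) exists if u lists v among its k nearest
    neighbours or vice versa, so every node keeps all k of its own
    neighbours.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    nn = spatial_knn_indices(coords, k)
    n = len(coords)
    src = np.repeat(np.arange(n), k)
    dst = nn.ravel()
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    return SpatialGraph(sample_id=sample_id, n_nodes=n, edges=edges,
                        coords=coords, k=k)


def _pearson_rows(a, b):
    """Pearson correlation of paired rows of two equal-shape 2D arrays."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    bad = denom == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} degenerate (constant) rows; "
                      "their correlations set to 0")
        r = np.where(bad, 0.0, r)
    return np.clip(r, -1.0, 1.0)


def edge_weight_pearson(y: np.ndarray, u: int, v: int) -> float:
    """Pearson correlation between the PC rows of units u and v."""
    return float(_pearson_rows(y[None, u], y[None, v])[0])


def edge_weight_snn(y: np.ndarray, u: int, v: int, k_snn: int,
                    _nn_cache=None) -> float:
    """Shared-nearest-neighbour weight |kNN(u) ∩ kNN(v)| / k_snn in PC space.

    Neighbour sets are self-inclusive (each point is its own nearest
    neighbour), so two points with identical PC rows score exactly 1 and
    points in far-separated clusters score 0.
    """
    if _nn_cache is None:
        _nn_cache = _expression_knn(y, k_snn)
    return len(np.intersect1d(_nn_cache[u], _nn_cache[v])) / k_snn


def _expression_knn(y, k_snn):
    """Self-inclusive k_snn-nearest sets in expression space; distance ties
    break by lower index, with the query point always ranked first."""
    if k_snn >= len(y):
        raise ValueError(f"k_snn={k_snn} must be < n_units={len(y)}")
    tree = cKDTree(y)
    m = min(len(y), k_snn + 8)
    dist, idx = tree.query(y, k=m)
    out = np.empty((len(y), k_snn), dtype=int)
    for i in range(len(y)):
        d, j = dist[i], idx[i]
        order = np.lexsort((np.where(j == i, -1, j), np.round(d, 12)))
        out[i] = j[order[:k_snn]]
    return out


def compute_edge_weights(graph: SpatialGraph, reduced: ReducedMatrix,
                         mode: str = "pearson", k_snn: int = 20) -> SpatialGraph:
    """Attach unsmoothed expression weights to every edge."""
    y = reduced.values
    if mode == "pearson":
        w = _pearson_rows(y[graph.edges[:, 0]], y[graph.edges[:, 1]])
    elif mode == "snn":
        cache = _expression_knn(y, k_snn)
        w = np.array([
            len(np.intersect1d(cache[u], cache[v])) / k_snn
            for u, v in graph.edges
        ])
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return replace(graph, weights=w)


def smoothed_edge_weights(graph: SpatialGraph, reduced: ReducedMatrix,
                          q: int) -> np.ndarray:
    """Neighbourhood-averaged edge weights.

    For edge (u, v) with spatial q-neighbourhoods Vu, Vv: the shared
    neighbours Vu ∩ Vv are excluded from both sides, the endpoint itself is
    added back, and the weight is the Pearson correlation between the
    component-wise means of Y over the two resulting sets. With q = 0 this
    reduces exactly to the pairwise endpoint correlation.
    """
    y = reduced.values
    if q < 0:
        raise ValueError("q must be >= 0")
    if q == 0:
        return _pearson_rows(y[graph.edges[:, 0]], y[graph.edges[:, 1]])
    nn = spatial_knn_indices(graph.coords, min(q, graph.n_nodes - 1))
    means_u = np.empty((graph.n_edges, y.shape[1]))
    means_v = np.empty((graph.n_edges, y.shape[1]))
    for e, (u, v) in enumerate(graph.edges):
        vu, vv = nn[u], nn[v]
        shared = np.intersect1d(vu, vv, assume_unique=True)
        su = np.setdiff1d(vu, shared, assume_unique=True)
        sv = np.setdiff1d(vv, shared, assume_unique=True)
        su = np.append(su[su != u], u)
        sv = np.append(sv[sv != v], v)
        means_u[e] = y[su].mean(axis=0)
        means_v[e] = y[sv].mean(axis=0)
    return _pearson_rows(means_u, means_v)


def prune_edges(graph: SpatialGraph, weights: np.ndarray, threshold: float):
    """Remove edges whose weight falls below ``threshold`` (kept iff >=).

    Nodes are never removed; isolated nodes are allowed. Returns the pruned
    graph and a report with the removal count and a weight histogram (the
    histogram supports choosing a data-driven threshold).
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != graph.n_edges:
        raise ValueError("weights do not align with edges")
    keep = weights >= threshold
    hist, bin_edges = np.histogram(weights, bins=20) if len(weights) else (
        np.array([]), np.array([]))
    report = {
        "n_edges_before": graph.n_edges,
        "n_removed": int((~keep).sum()),
        "threshold": float(threshold),
        "weight_histogram": hist.tolist(),
        "weight_bin_edges": bin_edges.tolist(),
    }
    pruned = replace(graph, edges=graph.edges[keep], weights=weights[keep])
    return pruned, report
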
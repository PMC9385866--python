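"""Neighbour graph and geodesic approximation.

Global distances under the Fisher information metric are approximated the
Isomap way: connect each case to its nearest neighbours, weight each edge by
the local FI segment distance, and run all-pairs shortest paths
(Floyd-Warshall by default) over the resulting graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra, floyd_warshall

from finnet.fisher import SegmentDistanceSpec, segment_distances
from finnet.posterior import PosteriorModel

__all__ = ["NeighbourGraph", "GeodesicDistances", "build_graph", "all_pairs_geodesic"]

_FORMAT_VERSION = 1


@dataclass
class NeighbourGraph:
    """Undirected graph with non-negative FI edge weights.

    ``edges`` holds each undirected edge once as (i, j) with i < j.
    ``augmented_edges`` records edges added to bridge disconnected
    components (indices into ``edges``).
    """

    n_nodes: int
    edges: np.ndarray            # (m, 2) int
    weights: np.ndarray          # (m,)
    k_neighbours: int
    symmetrised: bool = True
    augmented_edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if self.edges.shape[0] != self.weights.shape[0]:
            raise ValueError("edges and weights length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("edge weights must be non-negative")

    def to_sparse(self) -> csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        vals = np.concatenate([self.weights, self.weights])
        return coo_matrix((vals, (rows, cols)), shape=(self.n_nodes, self.n_nodes)).tocsr()

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.to_sparse(), directed=False)
        return n_comp == 1

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format": "finnet.graph",
            "version": _FORMAT_VERSION,
            "n_nodes": self.n_nodes,
            "edges": self.edges.tolist(),
            "weights": self.weights.tolist(),
            "k_neighbours": self.k_neighbours,
            "symmetrised": self.symmetrised,
            "augmented_edges": [[int(i), int(j), float(w)] for i, j, w in self.augmented_edges],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "NeighbourGraph":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "finnet.graph":
            raise ValueError(f"{path} is not a serialized neighbour graph")
        return cls(
            n_nodes=payload["n_nodes"],
            edges=np.asarray(payload["edges"], dtype=int).reshape(-1, 2),
            weights=np.asarray(payload["weights"], dtype=float),
            k_neighbours=payload["k_neighbours"],
            symmetrised=payload["symmetrised"],
            augmented_edges=[tuple(e) for e in payload["augmented_edges"]],
        )


@dataclass
class GeodesicDistances:
    """Dense all-pairs shortest-path distance matrix (a metric)."""

    matrix: np.ndarray
    method: str = "floyd-warshall"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("distance matrix must be square")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, self.matrix, delimiter=",")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "GeodesicDistances":
        return cls(matrix=np.loadtxt(path, delimiter=","))


def _knn_indices(features: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest Euclidean neighbours of each row (self
    excluded); ties broken by ascending case index for determinism."""
    n = features.shape[0]
    d2 = np.sum(features**2, axis=1)
    dist2 = d2[:, None] + d2[None, :] - 2.0 * (features @ features.T)
    np.fill_diagonal(dist2, np.inf)
    idx = np.arange(n)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((idx, dist2[i]))
        out[i] = order[:k]
    return out


def build_graph(
    features: np.ndarray,
    model: PosteriorModel,
    k: int = 10,
    spec: SegmentDistanceSpec = SegmentDistanceSpec(),
    n_bridge_candidates: int = 10,
) -> NeighbourGraph:
    """Symmetrised k-nearest-neighbour graph with FI edge weights.

    Neighbour candidates are selected by Euclidean distance in the input
    feature space (keeping FI evaluations O(nk)); edge weights are FI
    segment distances. Disconnected components are bridged by the cheapest
    FI-distance edge among the ``n_bridge_candidates`` Euclidean-closest
    inter-component pairs; every added edge is recorded.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cases")
    if not (0 < k < n):
        raise ValueError(f"k must satisfy 0 < k < n (got k={k}, n={n})")

    nbrs = _knn_indices(x, k)
    pairs = set()
    for i in range(n):
        for j in nbrs[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=int)
    weights = segment_distances(model, x[edges[:, 0]], x[edges[:, 1]], spec)
    # exact duplicates get exact zero-weight edges
    dup = np.all(x[edges[:, 0]] == x[edges[:, 1]], axis=1)
    weights[dup] = 0.0

    graph = NeighbourGraph(n_nodes=n, edges=edges, weights=weights, k_neighbours=k)

    n_comp, labels = connected_components(graph.to_sparse(), directed=False)
    augmented: list[tuple[int, int, float]] = []
    while n_comp > 1:
        best = None  # (weight, i, j)
        for a in range(n_comp):
            ia = np.flatnonzero(labels == a)
            for b in range(a + 1, n_comp):
                ib = np.flatnonzero(labels == b)
                # Euclidean-closest candidate pairs across the two components
                diff = x[ia][:, None, :] - x[ib][None, :, :]
                d2 = np.sum(diff**2, axis=2)
                flat = np.argsort(d2, axis=None, kind="stable")[:n_bridge_candidates]
                ra, rb = np.unravel_index(flat, d2.shape)
                cand_i, cand_j = ia[ra], ib[rb]
                w = segment_distances(model, x[cand_i], x[cand_j], spec)
                m = int(np.argmin(w))
                cand = (float(w[m]), int(cand_i[m]), int(cand_j[m]))
                if best is None or cand < best:
                    best = cand
        w, i, j = best
        i, j = min(i, j), max(i, j)
        graph.edges = np.vstack([graph.edges, [i, j]])
        graph.weights = np.append(graph.weights, w)
        augmented.append((i, j, w))
        n_comp, labels = connected_components(graph.to_sparse(), directed=False)

    graph.augmented_edges = augmented
    return graph


def all_pairs_geodesic(graph: NeighbourGraph, method: str = "floyd-warshall") -> GeodesicDistances:
    """All-pairs shortest-path distances over the neighbour graph.

    Floyd-Warshall is the reference algorithm; ``method="dijkstra"``
    (repeated single-source) gives identical output and scales better for
    large n.
    """
    sparse = graph.to_sparse()
    n_comp, _ = connected_components(sparse, directed=False)
    if n_comp != 1:
        raise ValueError(
            f"graph has {n_comp} connected components; build_graph performs augmentation"
        )
    if method == "floyd-warshall":
        dist = floyd_warshall(sparse, directed=False)
    elif method == "dijkstra":
        dist = dijkstra(sparse, directed=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    dist = np.asarray(dist, dtype=float)
    dist = np.minimum(dist, dist.T)  # enforce exact symmetry
    np.fill_diagonal(dist, 0.0)
    return GeodesicDistances(matrix=dist, method=method)
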
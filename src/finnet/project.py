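"""Out-of-sample projection of unseen cases into a trained latent space.

A test case never modifies the training structures: its local FI segment
distances to a few Euclidean-nearest training anchors are chained with the
training geodesic matrix to give approximate geodesic distances to every
training case, and those distances are converted to coordinates by the
Gower out-of-sample formula against the classical-MDS basis (falling back
to iterative least squares when the embedding was stress-refined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from finnet.embed import LatentEmbedding
from finnet.fisher import SegmentDistanceSpec, segment_distances
from finnet.geodesic import GeodesicDistances, NeighbourGraph
from finnet.posterior import PosteriorModel

__all__ = ["ProjectionResult", "test_to_train_distances", "place_in_embedding", "project_cases"]


@dataclass
class ProjectionResult:
    """Solved latent coordinates for one unseen case."""

    coordinates: np.ndarray
    distances: np.ndarray        # geodesic distances to all training cases
    anchors: np.ndarray          # training indices used for local segments
    residual: float              # RMS mismatch between solved and target distances
    case_id: Optional[str] = None


def test_to_train_distances(
    model: PosteriorModel,
    train_features: np.ndarray,
    graph: NeighbourGraph,
    train_geodesics: GeodesicDistances,
    test_case: np.ndarray,
    k: Optional[int] = None,
    spec: SegmentDistanceSpec = SegmentDistanceSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Approximate geodesic distances from one test case to every training case.

    The test case is linked to its ``k`` Euclidean-nearest training anchors
    by local FI segment distances; the distance to training case j is then
    min over anchors i of segment(test, i) + D_train(i, j). Returns
    (distances, anchor indices). ``k`` defaults to the graph's training k.
    """
    x = np.atleast_2d(np.asarray(train_features, dtype=float))
    t = np.asarray(test_case, dtype=float).reshape(-1)
    if t.shape[0] != x.shape[1]:
        raise ValueError(
            f"test case has {t.shape[0]} features, training matrix has {x.shape[1]}"
        )
    n = x.shape[0]
    if train_geodesics.n != n:
        raise ValueError("geodesic matrix size does not match training features")
    if k is None:
        k = graph.k_neighbours
    if not (0 < k <= n):
        raise ValueError(f"k must satisfy 0 < k <= n (got k={k}, n={n})")

    d2 = np.sum((x - t) ** 2, axis=1)
    anchors = np.lexsort((np.arange(n), d2))[:k]

    segs = segment_distances(model, np.tile(t, (k, 1)), x[anchors], spec)
    coincident = np.all(x[anchors] == t, axis=1)
    segs[coincident] = 0.0

    dist = np.min(segs[:, None] + train_geodesics.matrix[anchors, :], axis=0)
    return dist, anchors


# the name begins with "test_"; keep pytest from collecting it as a test
test_to_train_distances.__test__ = False  # type: ignore[attr-defined]


def place_in_embedding(
    embedding: LatentEmbedding,
    train_geodesics: GeodesicDistances,
    test_distances: np.ndarray,
    case_id: Optional[str] = None,
    anchors: Optional[np.ndarray] = None,
) -> ProjectionResult:
    """Solve for latent coordinates consistent with distances to the training set.

    Uses the standard distance-based out-of-sample formula for classical
    MDS: with B's eigenpairs (v_a, l_a), the a-th coordinate is
    v_a . (mu - delta^2) / (2 sqrt(l_a)) where mu holds the row means of
    the squared training distance matrix. Exact on Euclidean fixtures.
    When the embedding was SMACOF-refined the formula seeds an iterative
    least-squares polish against the refined coordinates.
    """
    delta = np.asarray(test_distances, dtype=float).reshape(-1)
    n = train_geodesics.n
    if delta.shape[0] != n:
        raise ValueError("test_distances length must equal the number of training cases")
    if embedding.n_cases != n:
        raise ValueError("embedding size does not match the geodesic matrix")
    coords = embedding.coordinates
    if np.allclose(coords, coords[0]):
        raise ValueError("degenerate training embedding: all coordinates coincide")

    mu = np.mean(train_geodesics.matrix**2, axis=1)
    b = 0.5 * (mu - delta**2)
    lam = embedding.basis_eigenvalues
    safe = np.where(lam > 0, np.sqrt(lam), np.inf)
    x = (embedding.basis.T @ b) / safe

    if embedding.refined:
        def objective(pos: np.ndarray) -> float:
            emb = np.sqrt(np.sum((coords - pos) ** 2, axis=1))
            return float(np.sum((emb - delta) ** 2))

        res = minimize(objective, x, method="L-BFGS-B")
        x = res.x

    emb_dist = np.sqrt(np.sum((coords - x) ** 2, axis=1))
    residual = float(np.sqrt(np.mean((emb_dist - delta) ** 2)))
    return ProjectionResult(
        coordinates=x,
        distances=delta,
        anchors=np.asarray([] if anchors is None else anchors, dtype=int),
        residual=residual,
        case_id=case_id,
    )


def project_cases(
    model: PosteriorModel,
    train_features: np.ndarray,
    graph: NeighbourGraph,
    train_geodesics: GeodesicDistances,
    embedding: LatentEmbedding,
    test_features: np.ndarray,
    k: Optional[int] = None,
    spec: SegmentDistanceSpec = SegmentDistanceSpec(),
    case_ids: Optional[list[str]] = None,
) -> list[ProjectionResult]:
    """Project each row of ``test_features`` independently (no test-test edges)."""
    test = np.atleast_2d(np.asarray(test_features, dtype=float))
    results = []
    for i, row in enumerate(test):
        dist, anchors = test_to_train_distances(
            model, train_features, graph, train_geodesics, row, k=k, spec=spec
        )
        cid = case_ids[i] if case_ids is not None else None
        results.append(
            place_in_embedding(embedding, train_geodesics, dist, case_id=cid, anchors=anchors)
        )
    return results
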
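"""Shared test helpers: oracle models and alignment/graph oracles.

Everything here is deliberately independent of the library code paths it is
used to check (brute force, closed forms, exhaustive enumeration).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import orthogonal_procrustes

from finnet.posterior import PosteriorModel


class IdentityFieldModel(PosteriorModel):
    """Mock posterior model whose Fisher information matrix is exactly the
    identity everywhere, so FI segment distances reduce to Euclidean ones.

    Uses d classes with uniform posteriors 1/d and constant per-class
    gradients g_c = sqrt(d) e_c, giving sum_c (1/d) d e_c e_c^T = I.
    """

    def __init__(self, n_inputs: int) -> None:
        self.n_inputs = n_inputs
        self.n_classes = n_inputs

    def predict_posteriors(self, features: np.ndarray) -> np.ndarray:
        x = self._check_input(features)
        return np.full((x.shape[0], self.n_classes), 1.0 / self.n_classes)

    def grad_log_posteriors(self, x: np.ndarray) -> np.ndarray:
        return np.sqrt(self.n_inputs) * np.eye(self.n_inputs)


def logistic_1d_model():
    """2-class model with p(1|x) = sigmoid(x) in one dimension."""
    from finnet.posterior import LinearSoftmaxModel

    return LinearSoftmaxModel(weights=np.array([[0.0, 1.0]]))


def procrustes_align(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rigid alignment (rotation/reflection + translation) of
    ``source`` onto ``target``; returns the aligned source coordinates."""
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    r, _ = orthogonal_procrustes(source - mu_s, target - mu_t)
    return (source - mu_s) @ r + mu_t


def brute_force_shortest_paths(n: int, edges: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Exhaustive enumeration of all simple paths (oracle for small graphs)."""
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    for (i, j), w in zip(edges, weights):
        adj[int(i)].append((int(j), float(w)))
        adj[int(j)].append((int(i), float(w)))

    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)

    def dfs(start: int, node: int, visited: set, length: float) -> None:
        if length < best[start, node]:
            best[start, node] = length
        for nxt, w in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                dfs(start, nxt, visited, length + w)
                visited.remove(nxt)

    for s in range(n):
        dfs(s, s, {s}, 0.0)
    return best


def is_connected(n: int, edges: np.ndarray) -> bool:
    """Brute-force BFS connectivity check."""
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in edges:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    seen = {0}
    frontier = [0]
    while frontier:
        node = frontier.pop()
        for nxtt in adj[node]:
            if nxtt not in seen:
                seen.add(nxtt)
                frontier.append(nxtt)
    return len(seen) == n
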
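"""Posterior-induced Fisher information metric.

At a point x the metric tensor is

    FI(x) = sum_c p(c|x) g_c g_c^T,      g_c = grad_x log p(c|x),

a symmetric PSD matrix that is large where class membership is sensitive to
small moves. The local distance between nearby points integrates the
associated quadratic differential form along the straight segment joining
them, approximated by a midpoint quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from finnet.posterior import PosteriorModel

__all__ = [
    "FisherField",
    "SegmentDistanceSpec",
    "fisher_matrix",
    "segment_distance",
    "segment_distances",
]


@dataclass(frozen=True)
class SegmentDistanceSpec:
    """Quadrature resolution and optional metric regularisation.

    ``ridge`` adds ridge*I to the metric; a tiny positive value (1e-8 is a
    good default for graph construction) prevents all local distances from
    collapsing to zero in posterior-flat regions.
    """

    n_steps: int = 10
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")


def fisher_matrix(model: PosteriorModel, x: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """The d x d Fisher information matrix at ``x`` (plus ridge*I)."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    grads = model.grad_log_posteriors(x)               # (C, d)
    if not np.all(np.isfinite(grads)):
        raise ValueError("non-finite log-posterior gradients at x")
    probs = model.predict_posteriors(x[None, :])[0]    # (C,)
    fi = grads.T @ (probs[:, None] * grads)
    fi = 0.5 * (fi + fi.T)
    if ridge:
        fi = fi + ridge * np.eye(fi.shape[0])
    return fi


class FisherField:
    """Callable context binding a posterior model to its metric tensor field."""

    def __init__(self, model: PosteriorModel, ridge: float = 0.0) -> None:
        if ridge < 0:
            raise ValueError("ridge must be non-negative")
        self.model = model
        self.ridge = ridge

    def fisher_at(self, x: np.ndarray) -> np.ndarray:
        return fisher_matrix(self.model, x, ridge=self.ridge)

    __call__ = fisher_at


def segment_distances(
    model: PosteriorModel,
    x: np.ndarray,
    y: np.ndarray,
    spec: SegmentDistanceSpec = SegmentDistanceSpec(),
) -> np.ndarray:
    """Local FI distances for a batch of point pairs (rows of x and y).

    Approximates integral_0^1 sqrt(d^T FI(x + t d) d) dt with d = y - x by
    a midpoint rule on ``spec.n_steps`` equally spaced midpoints. Only the
    quadratic form d^T FI d is needed, which equals
    sum_c p(c|.) (g_c . d)^2 + ridge |d|^2 — no d x d matrices are built.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have matching shapes")
    m, d = x.shape
    deltas = y - x
    n_steps = spec.n_steps

    ts = (np.arange(n_steps) + 0.5) / n_steps
    # midpoints for every (pair, step): shape (m * n_steps, d)
    points = (x[:, None, :] + ts[None, :, None] * deltas[:, None, :]).reshape(-1, d)
    rep_deltas = np.repeat(deltas, n_steps, axis=0)

    probs = model.predict_posteriors(points)
    dirs = model.directional_grad_log(points, rep_deltas)
    if not (np.all(np.isfinite(probs)) and np.all(np.isfinite(dirs))):
        raise ValueError("non-finite posterior or gradient along segment")
    quad = np.einsum("nc,nc->n", probs, dirs**2)
    if spec.ridge:
        quad = quad + spec.ridge * np.sum(rep_deltas**2, axis=1)
    quad = np.maximum(quad, 0.0)
    return np.sqrt(quad).reshape(m, n_steps).mean(axis=1)


def segment_distance(
    model: PosteriorModel,
    x: np.ndarray,
    y: np.ndarray,
    spec: SegmentDistanceSpec = SegmentDistanceSpec(),
) -> float:
    """Local FI distance between two points; 0 when x == y, symmetric in (x, y)."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if np.array_equal(x, y):
        return 0.0
    return float(segment_distances(model, x[None, :], y[None, :], spec)[0])
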
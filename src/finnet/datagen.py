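"""Synthetic multi-class feature data.

Gaussian-mixture feature vectors emulating dimension-reduced convolutional
features: one Gaussian blob per class, class means placed at the vertices of
a regular simplex so all pairwise separations are equal and controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = ["SyntheticSpec", "simplex_means", "generate_features"]


def simplex_means(n_classes: int, n_features: int, separation: float) -> np.ndarray:
    """Class means at the vertices of a regular simplex.

    The simplex lives in the first ``n_classes - 1`` feature dimensions
    (zeros elsewhere) and is scaled so that every pair of means is exactly
    ``separation`` apart in Euclidean distance.
    """
    if n_features < n_classes - 1:
        raise ValueError(
            f"n_features={n_features} too small to place a regular simplex "
            f"for {n_classes} classes (need at least {n_classes - 1})"
        )
    if n_classes == 1:
        return np.zeros((1, n_features))
    # Vertices e_i of the standard basis, centred, have pairwise distance
    # sqrt(2) and span an (n_classes-1)-dim subspace; express them in an
    # orthonormal basis of that subspace via SVD.
    verts = np.eye(n_classes) - 1.0 / n_classes
    u, s, _ = np.linalg.svd(verts, full_matrices=False)
    coords = (u[:, : n_classes - 1] * s[: n_classes - 1]) * (separation / np.sqrt(2.0))
    means = np.zeros((n_classes, n_features))
    means[:, : n_classes - 1] = coords
    return means


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic Gaussian-mixture generator.

    ``separation`` is the Euclidean distance between every pair of class
    means (ignored when ``class_means`` is given explicitly).
    ``within_class_sd`` is either a scalar (isotropic, shared) or one value
    per class. ``background_class`` optionally flags one class index whose
    dispersion is inflated by ``background_scale`` to mimic a heterogeneous
    background class.
    """

    n_cases: int
    n_classes: int = 5
    n_features: int = 10
    separation: float = 6.0
    within_class_sd: Union[float, Sequence[float]] = 1.0
    class_means: Optional[np.ndarray] = None
    class_proportions: Optional[Sequence[float]] = None
    background_class: Optional[int] = None
    background_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if self.n_classes <= 0:
            raise ValueError("n_classes must be positive")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        sds = np.atleast_1d(np.asarray(self.within_class_sd, dtype=float))
        if np.any(sds <= 0) or not np.all(np.isfinite(sds)):
            raise ValueError("within_class_sd must be positive and finite")
        if sds.size not in (1, self.n_classes):
            raise ValueError("within_class_sd must be scalar or one value per class")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if p.shape != (self.n_classes,):
                raise ValueError("class_proportions must have one entry per class")
            if np.any(p < 0):
                raise ValueError("class_proportions must be non-negative")
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError("class_proportions must sum to 1 (within 1e-12)")
        if self.class_means is not None:
            m = np.asarray(self.class_means, dtype=float)
            if m.shape != (self.n_classes, self.n_features):
                raise ValueError("class_means must be n_classes x n_features")
        if self.background_class is not None and not (
            0 <= self.background_class < self.n_classes
        ):
            raise ValueError("background_class out of range")

    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_proportions, dtype=float)

    def means(self) -> np.ndarray:
        if self.class_means is not None:
            return np.asarray(self.class_means, dtype=float)
        return simplex_means(self.n_classes, self.n_features, self.separation)

    def class_sds(self) -> np.ndarray:
        sds = np.atleast_1d(np.asarray(self.within_class_sd, dtype=float))
        if sds.size == 1:
            sds = np.full(self.n_classes, sds[0])
        else:
            sds = sds.copy()
        if self.background_class is not None:
            sds[self.background_class] *= self.background_scale
        return sds


def generate_features(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw a (features, labels) sample from the mixture described by ``spec``.

    A single generator is seeded once per call; identical specs give
    bitwise-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    props = spec.proportions()
    labels = rng.choice(spec.n_classes, size=spec.n_cases, p=props)
    means = spec.means()
    sds = spec.class_sds()
    noise = rng.standard_normal((spec.n_cases, spec.n_features))
    features = means[labels] + noise * sds[labels][:, None]
    return features, labels
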
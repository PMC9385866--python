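"""Kernel adjacency and latent embedding.

The geodesic distance matrix is converted to (i) a Gaussian radial kernel
adjacency A = exp(-D^2 / sigma_G^2), whose width sigma_G is the average
pairwise geodesic distance between points sharing the same predicted label,
and (ii) low-dimensional coordinates by classical (Torgerson)
multidimensional scaling, optionally refined by stress majorisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from finnet.geodesic import GeodesicDistances

__all__ = [
    "KernelAdjacency",
    "LatentEmbedding",
    "compute_sigma_g",
    "kernel_adjacency",
    "mds_embed",
]

_FORMAT_VERSION = 1


def _as_distance_matrix(distances) -> np.ndarray:
    if isinstance(distances, GeodesicDistances):
        return distances.matrix
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    return d


def compute_sigma_g(distances, predicted_labels: np.ndarray) -> float:
    """Mean geodesic distance over all unordered same-predicted-label pairs,
    pooled across labels."""
    d = _as_distance_matrix(distances)
    labels = np.asarray(predicted_labels).reshape(-1)
    if labels.shape[0] != d.shape[0]:
        raise ValueError("predicted_labels length must match the distance matrix")
    total = 0.0
    count = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 2:
            continue
        sub = d[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        total += sub[iu].sum()
        count += iu[0].size
    if count == 0:
        raise ValueError("no label has two or more members; sigma_G undefined")
    return total / count


@dataclass
class KernelAdjacency:
    """Gaussian radial kernel of geodesic distances: the FIN connection weights."""

    matrix: np.ndarray
    sigma_g: float
    predicted_labels: Optional[np.ndarray] = None

    def similarity(self, distance: np.ndarray) -> np.ndarray:
        return np.exp(-np.asarray(distance, dtype=float) ** 2 / self.sigma_g**2)


def kernel_adjacency(
    distances, sigma_g: float, predicted_labels: Optional[np.ndarray] = None
) -> KernelAdjacency:
    """A = exp(-D^2 / sigma_G^2), elementwise."""
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    d = _as_distance_matrix(distances)
    return KernelAdjacency(
        matrix=np.exp(-(d**2) / sigma_g**2),
        sigma_g=float(sigma_g),
        predicted_labels=None if predicted_labels is None else np.asarray(predicted_labels),
    )


@dataclass
class LatentEmbedding:
    """Low-dimensional coordinates from MDS on geodesic distances.

    ``eigenvalues`` are all eigenvalues of the double-centred inner-product
    matrix in non-increasing order; ``clamped_mass`` is the absolute sum of
    negative eigenvalues (clamped to zero before taking square roots), a
    diagnostic of how non-Euclidean the geodesic matrix was. ``basis``
    holds the top-m eigenvectors (sign convention applied) needed for
    out-of-sample projection.
    """

    coordinates: np.ndarray          # (n, m)
    eigenvalues: np.ndarray          # (n,), non-increasing
    stress: float
    basis: np.ndarray                # (n, m) eigenvectors
    basis_eigenvalues: np.ndarray    # (m,), clamped at 0
    clamped_mass: float = 0.0
    refined: bool = False
    seed: int = 0

    @property
    def n_cases(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format": "finnet.embedding",
            "version": _FORMAT_VERSION,
            "coordinates": self.coordinates.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "stress": self.stress,
            "basis": self.basis.tolist(),
            "basis_eigenvalues": self.basis_eigenvalues.tolist(),
            "clamped_mass": self.clamped_mass,
            "refined": self.refined,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "LatentEmbedding":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "finnet.embedding":
            raise ValueError(f"{path} is not a serialized embedding")
        return cls(
            coordinates=np.asarray(payload["coordinates"], dtype=float),
            eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
            stress=float(payload["stress"]),
            basis=np.asarray(payload["basis"], dtype=float),
            basis_eigenvalues=np.asarray(payload["basis_eigenvalues"], dtype=float),
            clamped_mass=float(payload["clamped_mass"]),
            refined=bool(payload["refined"]),
            seed=int(payload["seed"]),
        )


def _normalised_stress(coords: np.ndarray, target: np.ndarray) -> float:
    diff = coords[:, None, :] - coords[None, :, :]
    emb = np.sqrt(np.maximum(np.sum(diff**2, axis=2), 0.0))
    iu = np.triu_indices(target.shape[0], k=1)
    denom = np.sum(target[iu] ** 2)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(np.sum((emb[iu] - target[iu]) ** 2) / denom))


def _apply_sign_convention(coords: np.ndarray, basis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # flip each axis so its largest-magnitude coordinate is positive
    for a in range(coords.shape[1]):
        col = coords[:, a]
        if col.size and col[np.abs(col).argmax()] < 0:
            coords[:, a] = -col
            basis[:, a] = -basis[:, a]
    return coords, basis


def mds_embed(
    distances,
    m: int = 2,
    seed: int = 0,
    refine: bool = False,
) -> LatentEmbedding:
    """Classical (double-centred eigendecomposition) MDS in ``m`` dimensions.

    Negative eigenvalues of the centred inner-product matrix (which arise
    when the geodesic matrix is not exactly Euclidean) are clamped to zero;
    their absolute sum is reported as ``clamped_mass``. With
    ``refine=True``, the classical solution seeds a round of SMACOF stress
    majorisation (seed-controlled).
    """
    d = _as_distance_matrix(distances)
    n = d.shape[0]
    if not (0 < m < n):
        raise ValueError(f"m must satisfy 0 < m < n (got m={m}, n={n})")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite and non-negative")

    d2 = d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    b = 0.5 * (b + b.T)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    top_vals = np.maximum(eigvals[:m], 0.0)
    clamped_mass = float(np.abs(eigvals[eigvals < 0]).sum())
    basis = eigvecs[:, :m].copy()
    coords = basis * np.sqrt(top_vals)

    coords, basis = _apply_sign_convention(coords, basis)

    refined = False
    if refine:
        from sklearn.manifold import smacof

        coords, _ = smacof(
            d,
            n_components=m,
            init=coords,
            n_init=1,
            random_state=seed,
            metric=True,
            normalized_stress=False,
        )
        coords, basis = _apply_sign_convention(coords.copy(), basis)
        refined = True

    return LatentEmbedding(
        coordinates=coords,
        eigenvalues=eigvals,
        stress=_normalised_stress(coords, d),
        basis=basis,
        basis_eigenvalues=top_vals,
        clamped_mass=clamped_mass,
        refined=refined,
        seed=seed,
    )
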
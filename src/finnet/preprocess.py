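"""Feature standardisation and PCA with variance-retention thresholding."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = ["PCATransform", "fit_pca", "apply_pca"]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PCATransform:
    """A fitted linear projection: centre (optionally scale), then rotate.

    ``components`` has orthonormal columns (one per retained component);
    ``explained_variance_ratios`` is non-increasing and its cumulative sum
    first reaches ``variance_threshold`` at the last retained component.
    All arrays are read-only: test data must be transformed with the
    training mean and components, never by refitting.
    """

    mean: np.ndarray                        # (d,)
    components: np.ndarray                  # (d, k), orthonormal columns
    explained_variance_ratios: np.ndarray   # (k,)
    variance_threshold: float
    scale: Optional[np.ndarray] = None      # (d,) when standardised

    def __post_init__(self) -> None:
        for arr in (self.mean, self.components, self.explained_variance_ratios, self.scale):
            if arr is not None:
                arr.setflags(write=False)

    @property
    def n_features(self) -> int:
        return self.components.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def transform(self, features: np.ndarray) -> np.ndarray:
        return apply_pca(self, features)

    def inverse_transform(self, projected: np.ndarray) -> np.ndarray:
        projected = np.asarray(projected, dtype=float)
        x = projected @ self.components.T
        if self.scale is not None:
            x = x * self.scale
        return x + self.mean

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format": "finnet.pca",
            "version": _FORMAT_VERSION,
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratios": self.explained_variance_ratios.tolist(),
            "variance_threshold": self.variance_threshold,
            "scale": None if self.scale is None else self.scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "PCATransform":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "finnet.pca":
            raise ValueError(f"{path} is not a serialized PCA transform")
        return cls(
            mean=np.asarray(payload["mean"], dtype=float),
            components=np.asarray(payload["components"], dtype=float),
            explained_variance_ratios=np.asarray(
                payload["explained_variance_ratios"], dtype=float
            ),
            variance_threshold=float(payload["variance_threshold"]),
            scale=None if payload["scale"] is None else np.asarray(payload["scale"], dtype=float),
        )


def fit_pca(
    features: np.ndarray,
    variance_threshold: float = 0.9,
    standardise: bool = False,
) -> PCATransform:
    """Fit PCA keeping the smallest number of components whose cumulative
    explained-variance ratio reaches ``variance_threshold``.

    Centres by the training mean; rescaling to unit variance is off by
    default (``standardise=True`` enables it). Component signs are fixed so
    each component's largest-magnitude loading is positive, making the
    transform reproducible across runs and BLAS builds.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 cases to fit PCA")
    if d < 1:
        raise ValueError("need at least 1 feature")
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must be in (0, 1]")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")

    mean = x.mean(axis=0)
    centred = x - mean
    scale = None
    if standardise:
        scale = centred.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
        centred = centred / scale

    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    variances = svals**2
    total = variances.sum()
    if total <= 1e-12 * max(n, d):
        raise ValueError("feature matrix is constant: zero total variance")
    ratios = variances / total

    cumulative = np.cumsum(ratios)
    k = int(np.searchsorted(cumulative, variance_threshold - 1e-12)) + 1
    k = min(k, len(ratios))

    components = vt[:k].T
    # sign convention: largest-|loading| entry of each component positive
    flips = np.sign(components[np.abs(components).argmax(axis=0), np.arange(k)])
    flips[flips == 0] = 1.0
    components = components * flips

    return PCATransform(
        mean=mean,
        components=components,
        explained_variance_ratios=ratios[:k].copy(),
        variance_threshold=float(variance_threshold),
        scale=scale,
    )


def apply_pca(transform: PCATransform, features: np.ndarray) -> np.ndarray:
    """Project ``features`` with a previously fitted transform."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != transform.n_features:
        raise ValueError(
            f"feature count {x.shape[1]} does not match transform "
            f"({transform.n_features} features)"
        )
    centred = x - transform.mean
    if transform.scale is not None:
        centred = centred / transform.scale
    return centred @ transform.components
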
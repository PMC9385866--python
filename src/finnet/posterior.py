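"""Posterior-probability models.

The Fisher-information machinery only needs two things from a classifier:
class posteriors p(c|x) and gradients of log-posteriors with respect to the
inputs. :class:`PosteriorModel` is that contract. The bundled implementation
is a one-hidden-layer softmax MLP trained by mini-batch gradient descent
with classical momentum and L2 weight decay; closed-form linear-softmax and
constant models are provided as well (useful as analytic oracles).
"""

from __future__ import annotations

import abc
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "PosteriorModel",
    "MLPConfig",
    "MLPPosterior",
    "LinearSoftmaxModel",
    "ConstantPosteriorModel",
    "train_mlp",
    "predict_posteriors",
    "grad_log_posteriors",
]

_FORMAT_VERSION = 1


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PosteriorModel(abc.ABC):
    """Contract: anything exposing class posteriors and their input-gradients."""

    n_classes: int
    n_inputs: int

    @abc.abstractmethod
    def predict_posteriors(self, features: np.ndarray) -> np.ndarray:
        """Row-stochastic (n, C) posterior matrix for (n, d) inputs."""

    @abc.abstractmethod
    def grad_log_posteriors(self, x: np.ndarray) -> np.ndarray:
        """(C, d) matrix of gradients of log p(c|x) with respect to x."""

    def grad_log_posteriors_batch(self, features: np.ndarray) -> np.ndarray:
        """(n, C, d) stack of log-posterior input-gradients; loop fallback."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return np.stack([self.grad_log_posteriors(x) for x in features])

    def directional_grad_log(self, features: np.ndarray, deltas: np.ndarray) -> np.ndarray:
        """(n, C) directional derivatives (grad log p(c|x_i)) . delta_i.

        Subclasses may override with a cheaper path; consumed by the
        segment-distance quadrature, which only needs quadratic forms.
        """
        grads = self.grad_log_posteriors_batch(features)
        return np.einsum("ncd,nd->nc", grads, np.atleast_2d(deltas))

    def predict_labels(self, features: np.ndarray) -> np.ndarray:
        return self.predict_posteriors(features).argmax(axis=1)

    def _check_input(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.n_inputs:
            raise ValueError(
                f"input has {x.shape[1]} features, model expects {self.n_inputs}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        return x


@dataclass(frozen=True)
class MLPConfig:
    """Training configuration; defaults follow the reference setup
    (30 hidden units, learning rate 0.01, momentum 0.9, weight decay 0.2).

    ``weight_decay`` is applied as an L2 penalty coefficient on the weight
    matrices (biases exempt). 0.2 is large for an L2 coefficient and the
    exact decay scheme intended by the reference description is ambiguous;
    it is configurable for that reason.
    """

    hidden_units: int = 30
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.2
    max_epochs: int = 500
    batch_size: int = 32
    seed: int = 0
    hidden_activation: str = "logistic"

    def __post_init__(self) -> None:
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be non-negative")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if self.hidden_activation not in ("logistic", "tanh"):
            raise ValueError("hidden_activation must be 'logistic' or 'tanh'")


class MLPPosterior(PosteriorModel):
    """One-hidden-layer softmax MLP with analytic input-gradients.

    Forward pass: h = act(x W1 + b1), p = softmax(h W2 + b2).
    """

    def __init__(
        self,
        w1: np.ndarray,
        b1: np.ndarray,
        w2: np.ndarray,
        b2: np.ndarray,
        config: MLPConfig,
        loss_history: Optional[list[float]] = None,
    ) -> None:
        self.w1 = np.asarray(w1, dtype=float)   # (d, H)
        self.b1 = np.asarray(b1, dtype=float)   # (H,)
        self.w2 = np.asarray(w2, dtype=float)   # (H, C)
        self.b2 = np.asarray(b2, dtype=float)   # (C,)
        self.config = config
        self.loss_history = list(loss_history or [])
        self.n_inputs = self.w1.shape[0]
        self.n_classes = self.w2.shape[1]

    # -- forward ---------------------------------------------------------

    def _hidden(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.w1 + self.b1
        if self.config.hidden_activation == "tanh":
            return np.tanh(z)
        return _sigmoid(z)

    def _hidden_and_deriv(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = self._hidden(x)
        if self.config.hidden_activation == "tanh":
            return h, 1.0 - h**2
        return h, h * (1.0 - h)

    def predict_posteriors(self, features: np.ndarray) -> np.ndarray:
        x = self._check_input(features)
        return _softmax(self._hidden(x) @ self.w2 + self.b2)

    # -- input gradients (backprop to the inputs) ------------------------

    def grad_log_posteriors(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.shape[0] != self.n_inputs:
            raise ValueError(f"x has length {x.shape[0]}, expected {self.n_inputs}")
        return self.grad_log_posteriors_batch(x[None, :])[0]

    def grad_log_posteriors_batch(self, features: np.ndarray) -> np.ndarray:
        x = self._check_input(features)
        h, hp = self._hidden_and_deriv(x)
        p = _softmax(h @ self.w2 + self.b2)
        # d log p_c / d z2 = e_c - p ; back through W2, act', W1
        # T[n,c,:] = (W2[:,c] - W2 @ p_n) * hp_n   in hidden space
        t = self.w2.T[None, :, :] - (p @ self.w2.T)[:, None, :]
        t = t * hp[:, None, :]
        return t @ self.w1.T

    def directional_grad_log(self, features: np.ndarray, deltas: np.ndarray) -> np.ndarray:
        x = self._check_input(features)
        deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
        h, hp = self._hidden_and_deriv(x)
        p = _softmax(h @ self.w2 + self.b2)
        w = hp * (deltas @ self.w1)          # (n, H)
        q = w @ self.w2                      # (n, C)
        return q - (p * q).sum(axis=1, keepdims=True)

    # -- persistence -----------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format": "finnet.mlp",
            "version": _FORMAT_VERSION,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "config": self.config.__dict__,
            "loss_history": self.loss_history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "MLPPosterior":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "finnet.mlp":
            raise ValueError(f"{path} is not a serialized MLP model")
        return cls(
            w1=np.asarray(payload["w1"], dtype=float),
            b1=np.asarray(payload["b1"], dtype=float),
            w2=np.asarray(payload["w2"], dtype=float),
            b2=np.asarray(payload["b2"], dtype=float),
            config=MLPConfig(**payload["config"]),
            loss_history=payload.get("loss_history"),
        )


class LinearSoftmaxModel(PosteriorModel):
    """p(c|x) = softmax(W^T x + b) with closed-form input-gradients.

    grad_x log p(c|x) = w_c - sum_j p_j w_j.
    """

    def __init__(self, weights: np.ndarray, biases: Optional[np.ndarray] = None) -> None:
        self.weights = np.asarray(weights, dtype=float)   # (d, C)
        if self.weights.ndim != 2:
            raise ValueError("weights must be (n_inputs, n_classes)")
        self.n_inputs, self.n_classes = self.weights.shape
        self.biases = (
            np.zeros(self.n_classes) if biases is None else np.asarray(biases, dtype=float)
        )

    def predict_posteriors(self, features: np.ndarray) -> np.ndarray:
        x = self._check_input(features)
        return _softmax(x @ self.weights + self.biases)

    def grad_log_posteriors(self, x: np.ndarray) -> np.ndarray:
        return self.grad_log_posteriors_batch(np.asarray(x, dtype=float)[None, :])[0]

    def grad_log_posteriors_batch(self, features: np.ndarray) -> np.ndarray:
        x = self._check_input(features)
        p = self.predict_posteriors(x)
        return self.weights.T[None, :, :] - (p @ self.weights.T)[:, None, :]


class ConstantPosteriorModel(PosteriorModel):
    """Position-independent posteriors; all input-gradients are zero."""

    def __init__(self, probabilities: np.ndarray, n_inputs: int) -> None:
        p = np.asarray(probabilities, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("probabilities must be a 1-D simplex vector")
        self.probabilities = p
        self.n_classes = p.shape[0]
        self.n_inputs = n_inputs

    def predict_posteriors(self, features: np.ndarray) -> np.ndarray:
        x = self._check_input(features)
        return np.tile(self.probabilities, (x.shape[0], 1))

    def grad_log_posteriors(self, x: np.ndarray) -> np.ndarray:
        return np.zeros((self.n_classes, self.n_inputs))


def train_mlp(
    features: np.ndarray,
    labels: np.ndarray,
    config: Optional[MLPConfig] = None,
) -> MLPPosterior:
    """Train the bundled MLP by mini-batch gradient descent with momentum.

    Loss is categorical cross-entropy plus an L2 penalty of
    ``0.5 * weight_decay * (|W1|^2 + |W2|^2)`` (biases exempt). Weights are
    initialised from a scaled symmetric uniform distribution under the
    config seed; training is fully reproducible given the seed.
    """
    config = config or MLPConfig()
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).astype(int).reshape(-1)
    n, d = x.shape
    if y.shape[0] != n:
        raise ValueError("features and labels must have the same length")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes present in the labels")
    n_classes = int(classes.max()) + 1
    if classes.min() < 0:
        raise ValueError("labels must be non-negative integers")

    rng = np.random.default_rng(config.seed)
    hidden = config.hidden_units
    w1 = rng.uniform(-1.0, 1.0, size=(d, hidden)) / np.sqrt(d)
    b1 = np.zeros(hidden)
    w2 = rng.uniform(-1.0, 1.0, size=(hidden, n_classes)) / np.sqrt(hidden)
    b2 = np.zeros(n_classes)

    onehot = np.eye(n_classes)[y]
    model = MLPPosterior(w1, b1, w2, b2, config)
    vel = {k: np.zeros_like(getattr(model, k)) for k in ("w1", "b1", "w2", "b2")}
    lr, mom, decay = config.learning_rate, config.momentum, config.weight_decay
    loss_history: list[float] = []

    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, tb = x[idx], onehot[idx]
            m = xb.shape[0]

            h, hp = model._hidden_and_deriv(xb)
            p = _softmax(h @ model.w2 + model.b2)

            eps = 1e-12
            epoch_loss += -np.sum(tb * np.log(p + eps))

            dz2 = (p - tb) / m                       # (m, C)
            gw2 = h.T @ dz2 + decay * model.w2
            gb2 = dz2.sum(axis=0)
            dh = dz2 @ model.w2.T * hp               # (m, H)
            gw1 = xb.T @ dh + decay * model.w1
            gb1 = dh.sum(axis=0)

            for key, grad in (("w1", gw1), ("b1", gb1), ("w2", gw2), ("b2", gb2)):
                vel[key] = mom * vel[key] - lr * grad
                setattr(model, key, getattr(model, key) + vel[key])

        loss_history.append(
            epoch_loss / n
            + 0.5 * decay * (np.sum(model.w1**2) + np.sum(model.w2**2))
        )

    model.loss_history = loss_history
    return model


def predict_posteriors(model: PosteriorModel, features: np.ndarray) -> np.ndarray:
    """Functional alias for ``model.predict_posteriors``."""
    return model.predict_posteriors(features)


def grad_log_posteriors(model: PosteriorModel, x: np.ndarray) -> np.ndarray:
    """Functional alias for ``model.grad_log_posteriors``."""
    return model.grad_log_posteriors(x)
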
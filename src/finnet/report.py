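"""'Patient-like-me' retrieval, confusion tables and latent-space plots.

Retrieval ranks training cases by geodesic distance (training queries) or
projected geodesic distance (test queries) — not by 2-D embedded distance —
and reports the kernel similarity exp(-d^2/sigma_G^2) alongside labels and
pass-through metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "NeighbourReport",
    "nearest_neighbours",
    "misclassification_table",
    "render_latent_plot",
    "knn_purity",
]


@dataclass
class NeighbourReport:
    """Ranked nearest training cases for a query."""

    query_id: Optional[str]
    records: pd.DataFrame     # one row per neighbour, sorted by distance
    k: int
    majority_label: object
    vote_fractions: dict

    def to_csv(self, path: Union[str, Path]) -> None:
        self.records.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [f"query: {self.query_id}", f"k: {self.k}"]
        lines.append(f"majority label: {self.majority_label}")
        for lab, frac in sorted(self.vote_fractions.items(), key=lambda kv: -kv[1]):
            lines.append(f"  vote {lab}: {frac:.3f}")
        lines.append(self.records.to_string(index=False))
        return "\n".join(lines)


def nearest_neighbours(
    distances: np.ndarray,
    k: int,
    case_ids: Optional[Sequence] = None,
    true_labels: Optional[Sequence] = None,
    predicted_labels: Optional[Sequence] = None,
    sigma_g: Optional[float] = None,
    metadata: Optional[pd.DataFrame] = None,
    query_id: Optional[str] = None,
    exclude_index: Optional[int] = None,
) -> NeighbourReport:
    """Rank training cases by ascending distance to the query.

    ``exclude_index`` removes the query itself when it is a training case.
    Ties are broken by case index. ``metadata`` columns (joined positionally
    via ``case_id`` when present, else by row order) are passed through
    verbatim and never interpreted.
    """
    dist = np.asarray(distances, dtype=float).reshape(-1)
    n = dist.shape[0]
    eligible = np.arange(n)
    if exclude_index is not None:
        eligible = eligible[eligible != exclude_index]
    if not (0 < k <= eligible.size):
        raise ValueError(f"k must satisfy 0 < k <= {eligible.size} (got {k})")

    order = eligible[np.lexsort((eligible, dist[eligible]))][:k]

    ids = np.asarray(case_ids) if case_ids is not None else np.arange(n)
    frame = pd.DataFrame({"case_id": ids[order], "distance": dist[order]})
    if sigma_g is not None:
        frame["kernel_similarity"] = np.exp(-dist[order] ** 2 / sigma_g**2)
    if predicted_labels is not None:
        frame["predicted_label"] = np.asarray(predicted_labels)[order]
    if true_labels is not None:
        frame["true_label"] = np.asarray(true_labels)[order]
    if metadata is not None:
        meta = metadata.set_index("case_id") if "case_id" in metadata.columns else metadata
        joined = meta.reindex(frame["case_id"].values)
        for col in joined.columns:
            frame[col] = joined[col].values

    vote_col = "true_label" if true_labels is not None else (
        "predicted_label" if predicted_labels is not None else None
    )
    if vote_col is not None:
        counts = frame[vote_col].value_counts()
        vote_fractions = (counts / k).to_dict()
        majority = counts.index[0]
    else:
        vote_fractions, majority = {}, None

    return NeighbourReport(
        query_id=query_id,
        records=frame,
        k=k,
        majority_label=majority,
        vote_fractions=vote_fractions,
    )


def misclassification_table(
    true_labels: Sequence, predicted_labels: Sequence
) -> tuple[pd.DataFrame, float]:
    """Row-normalised confusion matrix (rows = true labels, each summing to
    one over classes it was predicted as) plus overall accuracy."""
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if not set(np.unique(y_true)) & set(np.unique(y_pred)):
        raise ValueError("true and predicted label sets are disjoint")

    labels = sorted(set(np.unique(y_true)) | set(np.unique(y_pred)))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    accuracy = float(np.trace(counts) / y_true.size)
    row_sums = counts.sum(axis=1, keepdims=True)
    normalised = np.divide(counts, row_sums, out=np.zeros_like(counts), where=row_sums > 0)
    return pd.DataFrame(normalised, index=labels, columns=labels), accuracy


def knn_purity(coordinates: np.ndarray, labels: Sequence, k: int = 10) -> float:
    """Mean fraction of each point's k nearest neighbours (Euclidean, self
    excluded, index tie-break) that share its label."""
    x = np.atleast_2d(np.asarray(coordinates, dtype=float))
    y = np.asarray(labels).reshape(-1)
    n = x.shape[0]
    if not (0 < k < n):
        raise ValueError(f"k must satisfy 0 < k < n (got k={k}, n={n})")
    d2 = np.sum(x**2, axis=1)
    dist2 = d2[:, None] + d2[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(dist2, np.inf)
    idx = np.arange(n)
    fractions = np.empty(n)
    for i in range(n):
        order = np.lexsort((idx, dist2[i]))[:k]
        fractions[i] = np.mean(y[order] == y[i])
    return float(fractions.mean())


def render_latent_plot(
    coordinates: np.ndarray,
    labels: Sequence,
    path: Optional[Union[str, Path]] = None,
    projections: Optional[np.ndarray] = None,
    highlight_ids: Optional[Sequence] = None,
    case_ids: Optional[Sequence] = None,
    title: Optional[str] = None,
):
    """Scatter plot of the latent space: translucent training cloud coloured
    by label, optional projected cases as black stars, optional highlighted
    cases circled in red. Deterministic for identical inputs. Saves to
    ``path`` when given (returning it), else returns the Figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    labs = np.asarray(labels)
    if coords.shape[0] < 1:
        raise ValueError("embedding must contain at least one case")

    fig, ax = plt.subplots(figsize=(7, 6))
    cmap = plt.get_cmap("tab10")
    for i, lab in enumerate(sorted(set(labs.tolist()))):
        mask = labs == lab
        ax.scatter(
            coords[mask, 0],
            coords[mask, 1],
            s=18,
            alpha=0.4,
            color=cmap(i % 10),
            label=str(lab),
        )
    if projections is not None:
        proj = np.atleast_2d(np.asarray(projections, dtype=float))
        ax.scatter(proj[:, 0], proj[:, 1], marker="*", s=90, color="black", label="projected")
    if highlight_ids is not None and len(highlight_ids) > 0:
        ids = np.asarray(case_ids) if case_ids is not None else np.arange(coords.shape[0])
        lookup = {v: i for i, v in enumerate(ids.tolist())}
        missing = [h for h in highlight_ids if h not in lookup]
        if missing:
            raise ValueError(f"unknown highlight id(s): {missing}")
        sel = [lookup[h] for h in highlight_ids]
        ax.scatter(
            coords[sel, 0],
            coords[sel, 1],
            facecolors="none",
            edgecolors="red",
            s=140,
            linewidths=1.5,
            label="highlighted",
        )
    ax.set_xlabel("latent dimension 1")
    ax.set_ylabel("latent dimension 2")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is None:
        return fig
    out = Path(path)
    fig.savefig(out, dpi=150, metadata={"CreationDate": None} if out.suffix == ".pdf" else None)
    plt.close(fig)
    return out
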
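"""Delimited-text I/O shared by all modules.

Case files are comma-separated with a header row: first column ``case_id``,
then one column per feature (``f000``, ``f001``, ...), and optionally a
final ``label`` column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["write_cases_csv", "read_cases_csv", "write_embedding_csv"]


def write_cases_csv(
    path: Union[str, Path],
    features: np.ndarray,
    labels: Optional[np.ndarray] = None,
    case_ids: Optional[Sequence] = None,
) -> Path:
    x = np.atleast_2d(np.asarray(features))
    n, d = x.shape
    ids = case_ids if case_ids is not None else [f"case{i:05d}" for i in range(n)]
    frame = pd.DataFrame(x, columns=[f"f{j:03d}" for j in range(d)])
    frame.insert(0, "case_id", list(ids))
    if labels is not None:
        frame["label"] = np.asarray(labels)
    out = Path(path)
    frame.to_csv(out, index=False)
    return out


def read_cases_csv(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Returns (case_ids, features, labels-or-None)."""
    frame = pd.read_csv(path)
    if "case_id" not in frame.columns:
        raise ValueError(f"{path}: missing case_id column")
    ids = frame["case_id"].to_numpy()
    labels = frame["label"].to_numpy() if "label" in frame.columns else None
    feat_cols = [c for c in frame.columns if c not in ("case_id", "label")]
    features = frame[feat_cols].to_numpy(dtype=float)
    return ids, features, labels


def write_embedding_csv(
    path: Union[str, Path],
    coordinates: np.ndarray,
    case_ids: Sequence,
    predicted_labels: Optional[np.ndarray] = None,
    true_labels: Optional[np.ndarray] = None,
    residuals: Optional[np.ndarray] = None,
) -> Path:
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    frame = pd.DataFrame(coords, columns=[f"z{j}" for j in range(coords.shape[1])])
    frame.insert(0, "case_id", list(case_ids))
    if predicted_labels is not None:
        frame["predicted_label"] = np.asarray(predicted_labels)
    if true_labels is not None:
        frame["true_label"] = np.asarray(true_labels)
    if residuals is not None:
        frame["residual"] = np.asarray(residuals)
    out = Path(path)
    frame.to_csv(out, index=False)
    return out
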
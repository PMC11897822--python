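"""Reading and writing the on-disk containers used across stages.

Feature matrices travel either as delimited text (header row of feature
names plus a designated label column) or as an ``.npz`` array container;
clinical tables as delimited text with a YAML schema alongside.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_da import LabelledFeatures
from .errors import ValidationError

__all__ = [
    "load_features",
    "save_features",
    "load_clinical",
]


def save_features(path, data: LabelledFeatures, label_column: str = "label") -> None:
    """Write features to ``.npz`` or delimited text depending on suffix."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            matrix=data.matrix,
            labels=data.labels,
            feature_names=np.asarray(
                data.feature_names
                or [f"f{i}" for i in range(data.n_features)]
            ),
        )
        return
    names = list(data.feature_names or (f"f{i}" for i in range(data.n_features)))
    frame = pd.DataFrame(data.matrix, columns=names)
    frame[label_column] = data.labels
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    frame.to_csv(path, sep=sep, index=False)


def load_features(path, label_column: str = "label") -> LabelledFeatures:
    """Read a feature container written by :func:`save_features`."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"features file not found: {path}")
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return LabelledFeatures(
                matrix=z["matrix"],
                labels=z["labels"],
                feature_names=tuple(str(n) for n in z["feature_names"]),
            )
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    if label_column not in frame.columns:
        raise ValidationError(
            f"label column {label_column!r} not found in {path}"
        )
    labels = frame[label_column].to_numpy()
    matrix = frame.drop(columns=[label_column])
    return LabelledFeatures(
        matrix=matrix.to_numpy(dtype=float),
        labels=labels,
        feature_names=tuple(matrix.columns),
    )


def load_clinical(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"clinical table not found: {path}")
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)
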
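"""Fusion of reduced image features with clinical variables.

Two strategies are supported: direct concatenation of encoded clinical
fields onto the reduced image features, and concatenation of clinical-text
embeddings that were themselves discriminant-reduced.  Encoding statistics
are always fitted on training samples only so that evaluation folds stay
leak-free.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core_da import DiscriminantBasis, project
from .errors import EmbeddingError, ValidationError

__all__ = [
    "ClinicalSchema",
    "ClinicalEncoder",
    "FusedVector",
    "fuse_concat",
    "fuse_embedded",
    "HashingTextEmbedder",
]

_FIELD_KINDS = ("numeric", "categorical", "text")
MISSING_CATEGORY = "__missing__"


@dataclass(frozen=True)
class ClinicalSchema:
    """Column -> kind mapping for a clinical table.

    Kinds are ``numeric``, ``categorical`` or ``text``; an optional
    ``id_column`` joins clinical rows to feature rows.
    """

    fields: dict[str, str]
    id_column: str | None = None

    def __post_init__(self) -> None:
        for col, kind in self.fields.items():
            if kind not in _FIELD_KINDS:
                raise ValidationError(
                    f"field {col!r} has unknown kind {kind!r}; "
                    f"expected one of {_FIELD_KINDS}"
                )

    @classmethod
    def from_yaml(cls, path) -> "ClinicalSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "fields" not in raw:
            raise ValidationError(f"schema file {path} must contain a 'fields' mapping")
        return cls(fields=dict(raw["fields"]), id_column=raw.get("id_column"))

    def to_yaml(self, path) -> None:
        payload: dict = {"fields": dict(self.fields)}
        if self.id_column is not None:
            payload["id_column"] = self.id_column
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


class ClinicalEncoder:
    """Numeric z-scoring and fixed-vocabulary one-hot encoding.

    Fit on a training table; transform never updates statistics.  Unknown
    categories at transform time map to all-zeros; missing numerics are
    imputed with the training mean and missing categoricals get a dedicated
    category.
    """

    def __init__(self, schema: ClinicalSchema):
        self.schema = schema
        self._means: dict[str, float] = {}
        self._stds: dict[str, float] = {}
        self._categories: dict[str, list] = {}
        self._fitted = False

    @property
    def is_fitted(self) -> bool:
        return self._fitted

    def fit(self, table: pd.DataFrame) -> "ClinicalEncoder":
        for col, kind in self.schema.fields.items():
            if col not in table.columns:
                raise ValidationError(f"clinical table is missing column {col!r}")
            if kind == "numeric":
                values = pd.to_numeric(table[col], errors="coerce")
                if np.isinf(values.to_numpy(dtype=float, na_value=np.nan)).any():
                    raise ValidationError(f"numeric column {col!r} has infinite values")
                mean = float(values.mean()) if values.notna().any() else 0.0
                std = float(values.std(ddof=0))
                self._means[col] = mean
                self._stds[col] = std if std > 0 else 1.0
            elif kind == "categorical":
                col_values = table[col].astype(object)
                cats = sorted(
                    {str(v) for v in col_values[col_values.notna()]}
                )
                if col_values.isna().any():
                    cats.append(MISSING_CATEGORY)
                self._categories[col] = cats
        self._fitted = True
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if not self._fitted:
            raise ValidationError("encoder must be fitted before transform")
        blocks: list[np.ndarray] = []
        for col, kind in self.schema.fields.items():
            if kind == "text":
                continue  # text fields are handled by the embedding strategy
            if col not in table.columns:
                raise ValidationError(f"clinical table is missing column {col!r}")
            if kind == "numeric":
                values = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
                if np.isinf(values).any():
                    raise ValidationError(f"numeric column {col!r} has infinite values")
                values = np.where(np.isnan(values), self._means[col], values)
                blocks.append(
                    ((values - self._means[col]) / self._stds[col])[:, None]
                )
            else:
                cats = self._categories[col]
                onehot = np.zeros((len(table), len(cats)))
                raw = table[col].astype(object)
                for i, v in enumerate(raw):
                    key = MISSING_CATEGORY if pd.isna(v) else str(v)
                    if key in cats:
                        onehot[i, cats.index(key)] = 1.0
                blocks.append(onehot)
        if not blocks:
            return np.zeros((len(table), 0))
        return np.hstack(blocks)

    def fit_transform(self, table: pd.DataFrame) -> np.ndarray:
        return self.fit(table).transform(table)

    @property
    def encoded_width(self) -> int:
        if not self._fitted:
            raise ValidationError("encoder must be fitted first")
        width = 0
        for col, kind in self.schema.fields.items():
            if kind == "numeric":
                width += 1
            elif kind == "categorical":
                width += len(self._categories[col])
        return width

    def categories(self, col: str) -> tuple:
        return tuple(self._categories[col])


@dataclass(frozen=True)
class FusedVector:
    """Concatenation of an image-feature block and a clinical block.

    ``image_slice`` / ``clinical_slice`` record the block boundaries so the
    original parts can be recovered exactly.
    """

    vector: np.ndarray
    image_slice: slice
    clinical_slice: slice

    @property
    def image_part(self) -> np.ndarray:
        return self.vector[self.image_slice]

    @property
    def clinical_part(self) -> np.ndarray:
        return self.vector[self.clinical_slice]


def _validate_finite(name: str, v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D vector")
    if not np.isfinite(v).all():
        raise ValidationError(f"{name} contains non-finite values")
    return v


def fuse_concat(reduced: np.ndarray, clinical: np.ndarray) -> FusedVector:
    """Strategy 1: append the encoded clinical vector to the reduced features.

    The image block is kept verbatim and always comes first.
    """
    reduced = _validate_finite("reduced features", reduced)
    clinical = _validate_finite("clinical vector", clinical)
    vector = np.concatenate([reduced, clinical])
    return FusedVector(
        vector=vector,
        image_slice=slice(0, reduced.size),
        clinical_slice=slice(reduced.size, vector.size),
    )


def fuse_embedded(
    reduced: np.ndarray,
    clinical_text: str,
    embedder,
    basis_cv: DiscriminantBasis,
) -> FusedVector:
    """Strategy 2: embed clinical text, reduce the embedding, then concatenate.

    ``embedder`` is any object with an ``embed(text) -> vector`` method;
    ``basis_cv`` is a discriminant basis fitted on training-fold embeddings.
    """
    reduced = _validate_finite("reduced features", reduced)
    try:
        embedding = np.asarray(embedder.embed(clinical_text), dtype=float)
    except Exception as exc:  # pragma: no cover - depends on the embedder
        raise EmbeddingError(f"embedder failed on input {clinical_text!r}") from exc
    reduced_cv = project(basis_cv, embedding)
    return fuse_concat(reduced, reduced_cv)


class HashingTextEmbedder:
    """Deterministic token-hashing embedder used as the shipped toy backend.

    Each whitespace token is hashed (salted SHA-256) to a coordinate and a
    sign; token vectors are accumulated and the result L2-normalized.  The
    same text always yields the same embedding, with no fitted state.
    """

    def __init__(self, dim: int = 32, salt: str = "fsda"):
        if dim < 1:
            raise ValidationError("embedding dimension must be >= 1")
        self.dim = dim
        self.salt = salt

    def embed(self, text: str) -> np.ndarray:
        out = np.zeros(self.dim)
        for token in str(text).lower().split():
            digest = hashlib.sha256(f"{self.salt}|{token}".encode()).digest()
            idx = int.from_bytes(digest[:4], "big") % self.dim
            sign = 1.0 if digest[4] % 2 == 0 else -1.0
            out[idx] += sign
        norm = np.linalg.norm(out)
        return out / norm if norm > 0 else out

    def embed_batch(self, texts) -> np.ndarray:
        return np.vstack([self.embed(t) for t in texts])
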
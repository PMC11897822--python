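"""Recursive Foley-Sammon discriminant directions for binary problems.

Classical Fisher analysis of a two-class problem yields a single direction
because the between-class scatter has rank one.  The Foley-Sammon recursion
lifts that limit: each new direction maximizes the Fisher criterion subject
to orthogonality with all previously extracted directions, giving an
ordered orthonormal basis whose span preserves discriminative information.
This module computes class statistics, the recursion itself, and the
resulting subspace projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import (
    DegenerateClassError,
    IllConditionedError,
    NoDiscriminantDirectionError,
    SubspaceExhausted,
    ValidationError,
)

__all__ = [
    "LabelledFeatures",
    "ClassStatistics",
    "DiscriminantBasis",
    "compute_class_statistics",
    "fisher_criterion",
    "first_direction",
    "next_direction",
    "fit_basis",
    "fit_basis_from_stats",
    "project",
    "default_ridge",
    "save_basis",
    "load_basis",
]

_EXHAUSTION_RTOL = 1e-10


@dataclass(frozen=True)
class LabelledFeatures:
    """An N x M feature matrix with binary labels.

    Class 1 is the class with the smaller label value; this ordering fixes
    the sign of the between-class direction.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels)
        if matrix.ndim != 2:
            raise ValidationError("feature matrix must be 2-D (samples x features)")
        if labels.shape != (matrix.shape[0],):
            raise ValidationError(
                f"labels shape {labels.shape} does not match {matrix.shape[0]} samples"
            )
        if not np.isfinite(matrix).all():
            raise ValidationError("feature matrix contains non-finite entries")
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise ValidationError(
                f"expected exactly 2 classes, found {uniq.size}: {uniq!r}"
            )
        if self.feature_names is not None and len(self.feature_names) != matrix.shape[1]:
            raise ValidationError("feature_names length does not match feature count")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def label_order(self) -> tuple:
        """Class labels sorted ascending; index 0 is class 1."""
        return tuple(np.unique(self.labels))

    @property
    def class_counts(self) -> tuple[int, int]:
        l1, l2 = self.label_order
        return int(np.sum(self.labels == l1)), int(np.sum(self.labels == l2))

    def class_matrix(self, which: int) -> np.ndarray:
        """Rows belonging to class ``which`` (1 or 2)."""
        return self.matrix[self.labels == self.label_order[which - 1]]


@dataclass(frozen=True)
class ClassStatistics:
    """First- and second-order statistics of a binary labelled sample.

    ``within_scatter`` is the beta-weighted combination of the per-class
    unbiased covariances; ``between_direction`` is the difference of class
    means, whose outer product is the (rank-one) between-class scatter.
    """

    between_direction: np.ndarray
    within_scatter: np.ndarray
    overall_mean: np.ndarray | None = None
    class_means: tuple[np.ndarray, np.ndarray] | None = None
    per_class_scatters: tuple[np.ndarray, np.ndarray] | None = None
    beta: float | None = None
    class_counts: tuple[int, int] | None = None
    within_mode: str = "as_printed"

    @property
    def n_features(self) -> int:
        return self.between_direction.shape[0]

    @property
    def between_scatter(self) -> np.ndarray:
        """Rank-one between-class scatter, materialized on demand."""
        s = self.between_direction
        return np.outer(s, s)

    @classmethod
    def from_scatter(
        cls, between_direction: np.ndarray, within_scatter: np.ndarray
    ) -> "ClassStatistics":
        """Build statistics directly from a scatter pair (for synthetic use)."""
        s = np.asarray(between_direction, dtype=float)
        w = np.asarray(within_scatter, dtype=float)
        if s.ndim != 1 or w.shape != (s.size, s.size):
            raise ValidationError("incompatible scatter dimensions")
        return cls(between_direction=s, within_scatter=w)


@dataclass(frozen=True)
class DiscriminantBasis:
    """Ordered orthonormal discriminant directions and their projection.

    ``projection`` stacks the directions as rows (L x M), so reducing a
    feature vector is a single matrix-vector product.
    """

    directions: np.ndarray  # (L, M), rows are unit vectors
    alphas: np.ndarray  # (L,) normalizing constants
    criterion_values: np.ndarray  # (L,) Fisher criterion per direction
    gram: np.ndarray  # (L-1, L-1) final system matrix, kept for audit
    within_mode: str = "as_printed"
    ridge: float = 0.0
    label_order: tuple = ()

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def n_features(self) -> int:
        return self.directions.shape[1]

    @property
    def projection(self) -> np.ndarray:
        return self.directions


class _WithinSolver:
    """Cholesky-backed application of the inverse regularized within-scatter.

    All "inverse" uses are linear solves against the factorization; the
    explicit inverse is never formed.
    """

    def __init__(self, within_scatter: np.ndarray, ridge: float = 0.0):
        if ridge < 0:
            raise ValidationError("ridge must be non-negative")
        m = within_scatter.shape[0]
        reg = within_scatter if ridge == 0 else within_scatter + ridge * np.eye(m)
        try:
            self._factor = cho_factor(reg, lower=True)
        except np.linalg.LinAlgError as exc:
            raise IllConditionedError(
                "regularized within-class scatter is not positive definite; "
                "increase the ridge"
            ) from exc
        self.matrix = reg

    def solve(self, b: np.ndarray) -> np.ndarray:
        return cho_solve(self._factor, b)


def default_ridge(within_scatter: np.ndarray) -> float:
    """Default Tikhonov level: 1e-6 * mean diagonal of the within-scatter.

    Chosen for the many-features / few-samples regime where the raw
    within-scatter is singular.
    """
    m = within_scatter.shape[0]
    return 1e-6 * float(np.trace(within_scatter)) / m


def compute_class_statistics(
    data: LabelledFeatures, within_mode: str = "as_printed"
) -> ClassStatistics:
    """Class means, between-class direction and within-class scatter.

    Per-class scatters are unbiased sample covariances (divisor N_j - 1).
    ``within_mode="as_printed"`` combines them with the cross weights
    beta = (N2-1)/(N1+N2-2) on the class-1 scatter and (1-beta) on the
    class-2 scatter; ``"pooled"`` uses the classical pooled covariance
    ((N1-1) S1 + (N2-1) S2) / (N1+N2-2).  The two coincide when N1 == N2.
    """
    if within_mode not in ("as_printed", "pooled"):
        raise ValidationError(f"unknown within_mode: {within_mode!r}")
    n1, n2 = data.class_counts
    if n1 < 2 or n2 < 2:
        raise DegenerateClassError(
            f"each class needs >= 2 samples for its scatter; got N1={n1}, N2={n2}"
        )
    y1 = data.class_matrix(1)
    y2 = data.class_matrix(2)
    mean1 = y1.mean(axis=0)
    mean2 = y2.mean(axis=0)
    s1 = np.cov(y1, rowvar=False, ddof=1)
    s2 = np.cov(y2, rowvar=False, ddof=1)
    s1 = np.atleast_2d(s1)
    s2 = np.atleast_2d(s2)
    beta = (n2 - 1) / (n1 + n2 - 2)
    if within_mode == "as_printed":
        within = beta * s1 + (1.0 - beta) * s2
    else:
        within = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    return ClassStatistics(
        between_direction=mean1 - mean2,
        within_scatter=within,
        overall_mean=data.matrix.mean(axis=0),
        class_means=(mean1, mean2),
        per_class_scatters=(s1, s2),
        beta=beta,
        class_counts=(n1, n2),
        within_mode=within_mode,
    )


def fisher_criterion(
    d: np.ndarray, stats: ClassStatistics, ridge: float = 0.0
) -> float:
    """Rayleigh-quotient ratio of projected between- to within-class scatter.

    Because the between-class scatter is rank one, the numerator collapses
    to the squared inner product with the between-class direction.  The
    value is invariant to rescaling of ``d``.
    """
    d = np.asarray(d, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0 or not np.isfinite(d).all():
        raise ValidationError("direction must be a finite non-zero vector")
    w = stats.within_scatter
    denom = float(d @ w @ d) + ridge * float(d @ d)
    if denom <= 1e-300 * norm**2 or denom <= 0:
        raise IllConditionedError("projected within-class scatter is numerically zero")
    num = float(stats.between_direction @ d) ** 2
    return num / denom


def _fix_sign(d: np.ndarray, s_b: np.ndarray) -> np.ndarray:
    """Deterministic sign: positive inner product with the between direction,
    falling back to a positive first non-zero coordinate on ties."""
    dot = float(s_b @ d)
    if dot > 0:
        return d
    if dot < 0:
        return -d
    nz = np.flatnonzero(d)
    if nz.size and d[nz[0]] < 0:
        return -d
    return d


def first_direction(
    stats: ClassStatistics, ridge: float = 0.0
) -> tuple[np.ndarray, float]:
    """Leading discriminant direction d1 and its normalizer alpha1.

    d1 is the unit-normalized solve of the within-scatter against the
    between-class direction — the classical Fisher direction.
    """
    solver = _WithinSolver(stats.within_scatter, ridge)
    return _first_direction(stats.between_direction, solver)


def _first_direction(s_b: np.ndarray, solver: _WithinSolver) -> tuple[np.ndarray, float]:
    if np.linalg.norm(s_b) == 0:
        raise NoDiscriminantDirectionError(
            "class means coincide; no discriminant direction exists"
        )
    u = solver.solve(s_b)
    norm = np.linalg.norm(u)
    if norm == 0 or not np.isfinite(norm):
        raise IllConditionedError("within-scatter solve produced a degenerate vector")
    alpha = 1.0 / norm
    return _fix_sign(u * alpha, s_b), alpha


def next_direction(
    stats: ClassStatistics, previous: DiscriminantBasis, ridge: float | None = None
) -> tuple[np.ndarray, float]:
    """Next discriminant direction given >= 1 already-extracted directions.

    Maximizes the Fisher criterion over the orthogonal complement of the
    previous directions.  Raises :class:`SubspaceExhausted` when no
    direction with positive discriminative value remains.
    """
    if previous.n_directions < 1:
        raise ValidationError("previous basis must contain at least one direction")
    if ridge is None:
        ridge = previous.ridge
    solver = _WithinSolver(stats.within_scatter, ridge)
    d, alpha, _ = _next_direction(
        stats.between_direction,
        solver,
        previous.directions,
        float(previous.alphas[0]),
    )
    return d, alpha


def _next_direction(
    s_b: np.ndarray,
    solver: _WithinSolver,
    directions: np.ndarray,
    alpha1: float,
) -> tuple[np.ndarray, float, np.ndarray]:
    """One recursion step; returns (d_n, alpha_n, gram matrix used)."""
    n_prev = directions.shape[0]
    # Gram system: entries d_i^T S_W^{-1} d_j, computed via solves.
    t = solver.solve(directions.T)  # (M, n_prev)
    gram = directions @ t
    rhs = np.zeros(n_prev)
    rhs[0] = 1.0 / alpha1
    try:
        coef = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError as exc:
        raise IllConditionedError("discriminant Gram system is singular") from exc
    braced = s_b - directions.T @ coef
    if np.linalg.norm(braced) < _EXHAUSTION_RTOL * np.linalg.norm(s_b):
        raise SubspaceExhausted(
            f"no discriminant direction beyond the first {n_prev} exists"
        )
    u = solver.solve(braced)
    norm = np.linalg.norm(u)
    if norm == 0 or not np.isfinite(norm):
        raise IllConditionedError("within-scatter solve produced a degenerate vector")
    alpha = 1.0 / norm
    return _fix_sign(u * alpha, s_b), alpha, gram


def fit_basis_from_stats(
    stats: ClassStatistics,
    n_directions: int,
    ridge: float | None = None,
    label_order: tuple = (),
) -> DiscriminantBasis:
    """Run the full recursion on precomputed statistics."""
    if n_directions < 1:
        raise ValidationError("number of directions must be >= 1")
    if ridge is None:
        ridge = default_ridge(stats.within_scatter)
    solver = _WithinSolver(stats.within_scatter, ridge)
    s_b = stats.between_direction
    d1, alpha1 = _first_direction(s_b, solver)
    directions = [d1]
    alphas = [alpha1]
    gram = np.zeros((0, 0))
    for n in range(2, n_directions + 1):
        try:
            d, alpha, gram = _next_direction(
                s_b, solver, np.asarray(directions), alpha1
            )
        except SubspaceExhausted:
            warnings.warn(
                f"discriminant subspace exhausted after {len(directions)} of "
                f"{n_directions} requested directions; basis truncated",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        directions.append(d)
        alphas.append(alpha)
    directions = np.asarray(directions)
    crit = np.array([fisher_criterion(d, stats, ridge=ridge) for d in directions])
    return DiscriminantBasis(
        directions=directions,
        alphas=np.asarray(alphas),
        criterion_values=crit,
        gram=gram,
        within_mode=stats.within_mode,
        ridge=float(ridge),
        label_order=tuple(label_order),
    )


def fit_basis(
    data: LabelledFeatures,
    n_directions: int = 10,
    within_mode: str = "as_printed",
    ridge: float | None = None,
) -> DiscriminantBasis:
    """Fit an ``n_directions``-dimensional discriminant basis to labelled data.

    ``ridge=None`` selects :func:`default_ridge`.  If the recursion exhausts
    the discriminative subspace early the basis is truncated with a warning.
    """
    stats = compute_class_statistics(data, within_mode=within_mode)
    return fit_basis_from_stats(
        stats, n_directions, ridge=ridge, label_order=data.label_order
    )


def project(basis: DiscriminantBasis, y: np.ndarray) -> np.ndarray:
    """Project feature vector(s) onto the discriminant subspace.

    Accepts a single length-M vector or an (N, M) batch; returns length-L
    or (N, L) accordingly.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != basis.n_features:
        raise ValidationError(
            f"feature dimension {y.shape[-1]} does not match basis "
            f"dimension {basis.n_features}"
        )
    # einsum keeps per-row summation order independent of batch size, so
    # batch and row-wise projection agree to the bit
    if y.ndim == 1:
        return np.einsum("m,lm->l", y, basis.projection)
    if y.ndim == 2:
        return np.einsum("nm,lm->nl", y, basis.projection)
    raise ValidationError("input must be 1-D or 2-D")


def save_basis(path, basis: DiscriminantBasis) -> None:
    """Persist a fitted basis to an ``.npz`` container."""
    np.savez(
        path,
        projection=basis.directions,
        alphas=basis.alphas,
        criterion_values=basis.criterion_values,
        gram=basis.gram,
        within_mode=np.array(basis.within_mode),
        ridge=np.array(basis.ridge),
        label_order=np.asarray(basis.label_order),
    )


def load_basis(path) -> DiscriminantBasis:
    with np.load(path, allow_pickle=False) as z:
        return DiscriminantBasis(
            directions=z["projection"],
            alphas=z["alphas"],
            criterion_values=z["criterion_values"],
            gram=z["gram"],
            within_mode=str(z["within_mode"]),
            ridge=float(z["ridge"]),
            label_order=tuple(z["label_order"].tolist()),
        )
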
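"""Cross-validated comparison of feature-reduction and fusion arms.

Reproduces the comparison protocol: six arms (original / PCA-reduced /
discriminant-reduced features, each with and without clinical variables),
stratified k-fold evaluation, and ACC/AUC reported as mean +/- std over
folds.  Reducers and clinical encoders are fitted inside each training
fold only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .core_da import DiscriminantBasis, LabelledFeatures, fit_basis, project
from .errors import ValidationError
from .fusion import ClinicalEncoder, ClinicalSchema

__all__ = [
    "ARMS",
    "LinearClassifier",
    "MarginClassifier",
    "train_classifier",
    "predict_scores",
    "cross_validate",
    "EvaluationReport",
]

ARMS = ("original", "original+CV", "PCA", "PCA+CV", "DA", "DA+CV")


@dataclass(frozen=True)
class LinearClassifier:
    """A single fully connected layer: per-class score columns plus bias."""

    weights: np.ndarray  # (D, c)
    bias: np.ndarray  # (c,)
    classes: tuple

    @property
    def n_classes(self) -> int:
        return self.weights.shape[1]

    @property
    def input_dim(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class MarginClassifier:
    """Soft-margin kernel classifier wrapper exposing decision scores."""

    model: SVC
    classes: tuple


def train_classifier(
    Z: np.ndarray,
    labels: np.ndarray,
    kind: str = "margin",
    seed: int = 0,
    c_grid: tuple[float, ...] | None = (0.1, 1.0, 10.0),
):
    """Train the final-stage classifier on fused vectors.

    ``margin`` fits an RBF soft-margin classifier, with the cost parameter
    selected by a small inner grid search when ``c_grid`` has more than one
    value.  ``linear`` fits a regularized logistic model and repackages it
    as an explicit weight matrix with one column per class, which the CAM
    path requires.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(np.unique(labels))
    if len(classes) < 2:
        raise ValidationError("training data contains a single class")
    for cls in classes:
        if np.sum(labels == cls) < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 samples")
    if kind == "margin":
        base = SVC(kernel="rbf", gamma="scale", random_state=seed)
        if c_grid and len(c_grid) > 1:
            n_min = min(int(np.sum(labels == c)) for c in classes)
            inner = min(3, n_min)
            if inner >= 2:
                search = GridSearchCV(
                    base,
                    {"C": list(c_grid)},
                    cv=StratifiedKFold(inner, shuffle=True, random_state=seed),
                    n_jobs=1,
                )
                search.fit(Z, labels)
                return MarginClassifier(model=search.best_estimator_, classes=classes)
        base.fit(Z, labels)
        return MarginClassifier(model=base, classes=classes)
    if kind == "linear":
        model = LogisticRegression(max_iter=2000)
        model.fit(Z, labels)
        w = model.coef_[0]  # (D,) score direction of classes[1]
        b = float(model.intercept_[0])
        weights = np.column_stack([-w / 2.0, w / 2.0])
        bias = np.array([-b / 2.0, b / 2.0])
        return LinearClassifier(weights=weights, bias=bias, classes=classes)
    raise ValidationError(f"unknown classifier kind: {kind!r}")


def predict_scores(classifier, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class scores and predicted labels.

    For the linear kind the scores are W^T z + bias and ties resolve to the
    lower class index; for the margin kind the binary decision function is
    expanded to two antisymmetric columns.
    """
    Z = np.asarray(Z, dtype=float)
    single = Z.ndim == 1
    if single:
        Z = Z[None, :]
    if isinstance(classifier, LinearClassifier):
        if Z.shape[1] != classifier.input_dim:
            raise ValidationError(
                f"input dim {Z.shape[1]} does not match classifier "
                f"dim {classifier.input_dim}"
            )
        scores = Z @ classifier.weights + classifier.bias
    elif isinstance(classifier, MarginClassifier):
        df = classifier.model.decision_function(Z)
        scores = np.column_stack([-df, df]) if df.ndim == 1 else df
    else:
        raise ValidationError(f"unsupported classifier type: {type(classifier)!r}")
    idx = np.argmax(scores, axis=1)  # argmax takes the lower index on ties
    labels = np.asarray(classifier.classes)[idx]
    if single:
        return scores[0], labels[0]
    return scores, labels


def _positive_scores(classifier, Z: np.ndarray) -> np.ndarray:
    """Continuous score for the positive (second-in-order) class."""
    scores, _ = predict_scores(classifier, np.atleast_2d(Z))
    return scores[:, 1] - scores[:, 0]


class _IdentityReducer:
    def fit(self, X, y):
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)


class _PCAReducer:
    """Training-fold PCA to the same dimensionality as the discriminant arm."""

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X, y):
        k = min(self.n_components, min(X.shape) - 1)
        self._pca = PCA(n_components=max(k, 1), svd_solver="full")
        self._pca.fit(X)
        return self

    def transform(self, X):
        return self._pca.transform(X)


class _DAReducer:
    def __init__(self, n_directions: int, within_mode: str, ridge: float | None):
        self.n_directions = n_directions
        self.within_mode = within_mode
        self.ridge = ridge

    def fit(self, X, y):
        data = LabelledFeatures(matrix=X, labels=y)
        self.basis_: DiscriminantBasis = fit_basis(
            data, self.n_directions, within_mode=self.within_mode, ridge=self.ridge
        )
        return self

    def transform(self, X):
        return project(self.basis_, X)


def _make_reducer(arm: str, n_directions: int, within_mode: str, ridge: float | None):
    base = arm.split("+")[0]
    if base == "original":
        return _IdentityReducer()
    if base == "PCA":
        return _PCAReducer(n_directions)
    if base == "DA":
        return _DAReducer(n_directions, within_mode, ridge)
    raise ValidationError(f"unknown arm: {arm!r}")


@dataclass
class EvaluationReport:
    """Per-arm fold metrics plus the configuration that produced them."""

    fold_metrics: dict  # arm -> {"acc": [...], "auc": [...]}
    config: dict
    positive_label: object

    def mean(self, arm: str, metric: str) -> float:
        return float(np.mean(self.fold_metrics[arm][metric]))

    def std(self, arm: str, metric: str) -> float:
        return float(np.std(self.fold_metrics[arm][metric]))

    def summary(self) -> dict:
        return {
            arm: {
                metric: {
                    "mean": self.mean(arm, metric),
                    "std": self.std(arm, metric),
                    "folds": list(map(float, values)),
                }
                for metric, values in metrics.items()
            }
            for arm, metrics in self.fold_metrics.items()
        }

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "positive_label": str(self.positive_label),
            "results": self.summary(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for arm, metrics in self.fold_metrics.items():
            for metric in metrics:
                rows.append(
                    {
                        "arm": arm,
                        "metric": metric,
                        "mean": self.mean(arm, metric),
                        "std": self.std(arm, metric),
                    }
                )
        return pd.DataFrame(rows)


def cross_validate(
    features: LabelledFeatures,
    clinical: pd.DataFrame | None = None,
    schema: ClinicalSchema | None = None,
    arms: tuple[str, ...] = ("DA", "DA+CV"),
    folds: int = 5,
    seed: int = 0,
    n_directions: int = 10,
    classifier: str = "margin",
    within_mode: str = "as_printed",
    ridge: float | None = None,
) -> EvaluationReport:
    """Stratified k-fold evaluation of the requested arms.

    Every fold refits the reducer, the clinical encoder and the classifier
    on the training split only.  AUC uses the continuous score of the
    positive class, taken as the second label in sorted order.
    """
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    for arm in arms:
        if arm not in ARMS:
            raise ValidationError(f"unknown arm {arm!r}; valid arms: {ARMS}")
        if arm.endswith("+CV") and (clinical is None or schema is None):
            raise ValidationError(f"arm {arm!r} requires a clinical table and schema")
    X = features.matrix
    y = features.labels
    counts = features.class_counts
    if min(counts) < folds:
        raise ValidationError(
            f"cannot stratify {folds} folds with class counts {counts}"
        )
    positive_label = features.label_order[1]
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics: dict = {arm: {"acc": [], "auc": []} for arm in arms}
    for train_idx, test_idx in splitter.split(X, y):
        X_tr, X_te = X[train_idx], X[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        for arm in arms:
            reducer = _make_reducer(arm, n_directions, within_mode, ridge)
            reducer.fit(X_tr, y_tr)
            Z_tr = reducer.transform(X_tr)
            Z_te = reducer.transform(X_te)
            if arm.endswith("+CV"):
                encoder = ClinicalEncoder(schema)
                encoder.fit(clinical.iloc[train_idx])
                Z_tr = np.hstack([Z_tr, encoder.transform(clinical.iloc[train_idx])])
                Z_te = np.hstack([Z_te, encoder.transform(clinical.iloc[test_idx])])
            model = train_classifier(Z_tr, y_tr, kind=classifier, seed=seed)
            _, pred = predict_scores(model, Z_te)
            fold_metrics[arm]["acc"].append(accuracy_score(y_te, pred))
            fold_metrics[arm]["auc"].append(
                roc_auc_score(y_te == positive_label, _positive_scores(model, Z_te))
            )
    config = {
        "arms": list(arms),
        "folds": folds,
        "seed": seed,
        "n_directions": n_directions,
        "classifier": classifier,
        "within_mode": within_mode,
        "ridge": ridge,
    }
    return EvaluationReport(
        fold_metrics=fold_metrics, config=config, positive_label=positive_label
    )
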
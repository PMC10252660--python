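"""Single-source model fitting: SVM, random forest and neural network.

Each model is tuned by stratified cross-validated accuracy over a small
grid, refit on the full training series at the best setting, and wrapped
with its feature list so prediction is only possible on inputs carrying
the same features.  Grids are ordered simple-to-complex and ties resolve
to the first (simplest) best setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureMatrix
from .layers import RESPONDER

ALGORITHMS = ("svm", "random_forest", "neural_network")

#: Default tuning grids (config-swappable).  SVM kernel width starts from
#: the median heuristic; RF mtry spans sqrt(p) and p/3.
DEFAULT_GRIDS = {
    "svm": {"clf__C": [0.25, 1.0, 4.0]},
    "random_forest": {},  # mtry grid is data-dependent; built in fit
    "neural_network": {
        "clf__hidden_layer_sizes": [(3,), (5,), (7,)],
        "clf__alpha": [0.1, 0.01],
    },
}


@dataclass
class FittedModel:
    algorithm: str
    feature_ids: tuple[str, ...]
    hyperparameters: dict
    estimator: object  # fitted sklearn pipeline
    seed: int
    cv_folds: int
    classes: tuple[str, ...] = ()
    tuning_grid: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "FittedModel":
        return joblib.load(path)


def _median_heuristic_gamma(Z: np.ndarray) -> float:
    """RBF kernel width from the median pairwise distance of the
    (standardized) training points."""
    if Z.shape[0] > 300:
        Z = Z[:300]
    d = pdist(Z)
    med = float(np.median(d[d > 0])) if (d > 0).any() else 1.0
    return 1.0 / (2.0 * med**2)


def _build_pipeline(algorithm: str, seed: int, gamma: float | None, p: int):
    if algorithm == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", gamma=gamma if gamma else "scale",
                            random_state=seed)),
            ]
        )
    if algorithm == "random_forest":
        return Pipeline(
            [("clf", RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1))]
        )
    if algorithm == "neural_network":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", MLPClassifier(max_iter=2000, random_state=seed)),
            ]
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def fit_single_source(
    X_train: FeatureMatrix,
    y_train: dict[str, str] | list[str],
    algorithm: str,
    tuning_grid: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> FittedModel:
    """Grid-searched fit of one algorithm on one feature layer.

    ``y_train`` maps sample id to class label (or lists labels in sample
    order).  Deterministic under ``seed``.
    """
    if isinstance(y_train, dict):
        y = np.array([y_train[s] for s in X_train.sample_ids])
    else:
        y = np.array(list(y_train))
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    M = X_train.values.T
    if tuning_grid is None:
        tuning_grid = dict(DEFAULT_GRIDS[algorithm])
        if algorithm == "random_forest":
            p = M.shape[1]
            mtry = sorted({max(1, int(np.sqrt(p))), max(1, p // 3)})
            tuning_grid = {"clf__max_features": mtry}
    if not tuning_grid or any(len(v) == 0 for v in tuning_grid.values()):
        raise ValueError("degenerate tuning grid")
    gamma = None
    if algorithm == "svm":
        sd = M.std(axis=0)
        Z = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        gamma = _median_heuristic_gamma(Z)
    pipe = _build_pipeline(algorithm, seed, gamma, M.shape[1])
    n_min = min(np.sum(y == c) for c in classes)
    folds = max(2, min(cv_folds, int(n_min)))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, tuning_grid, scoring="accuracy", cv=cv, n_jobs=1)
    search.fit(M, y)
    return FittedModel(
        algorithm=algorithm,
        feature_ids=tuple(X_train.feature_ids),
        hyperparameters=dict(search.best_params_),
        estimator=search.best_estimator_,
        seed=seed,
        cv_folds=folds,
        classes=tuple(classes),
        tuning_grid=tuning_grid,
    )


def predict(model: FittedModel, X: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Labels and continuous scores for each sample of *X*.

    Scores are oriented so that higher means predicted responder (when a
    'responder' class is present; otherwise higher means the
    lexicographically last class).
    """
    missing = [f for f in model.feature_ids if f not in set(X.feature_ids)]
    if missing:
        raise KeyError(f"input is missing model features: {missing[:5]}")
    M = X.subset_features(list(model.feature_ids)).values.T
    est = model.estimator
    labels = est.predict(M)
    positive = RESPONDER if RESPONDER in model.classes else model.classes[-1]
    clf_classes = list(est.classes_)
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(M)
        scores = proba[:, clf_classes.index(positive)]
    else:
        raw = est.decision_function(M)
        scores = raw if clf_classes[-1] == positive else -raw
    return labels, np.asarray(scores, dtype=float)
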
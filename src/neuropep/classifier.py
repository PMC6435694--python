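"""Binary classifiers over peptide feature matrices.

Five algorithm families mirror the study's machine-learning setup:

* ``svm_rbf`` — RBF-kernel support vector machine with kernel width ``g``,
  regularization ``c`` and positive-class cost factor ``j`` (``j`` scales
  the misclassification cost of positives relative to negatives).
* ``random_forest`` — ``ntree`` trees.
* ``decision_tree`` — pruned decision tree (``m`` = minimum leaf size; the
  pruning-confidence ``c`` is recorded for provenance but the sklearn tree
  is controlled by ``m``).
* ``naive_bayes`` — Gaussian naive Bayes.
* ``linear_margin`` — a linear-kernel margin classifier (the stand-in for
  WEKA's SMO; exact WEKA behaviour is not reproduced).

Scores are signed margins for margin-based learners and ``2*p(pos) - 1``
for probabilistic ones, so threshold 0 is a sensible default everywhere.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
import sklearn
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import cross_validate

ALGORITHMS = ("svm_rbf", "random_forest", "decision_tree", "naive_bayes", "linear_margin")

#: Default RBF grid: g log-spaced over [1e-4, 10], c in 1..15, j in 1..5.
DEFAULT_SVM_GRID: dict[str, list] = {
    "g": [1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 0.1, 0.5, 1.0, 5.0, 10.0],
    "c": list(range(1, 16)),
    "j": list(range(1, 6)),
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm name plus its hyperparameters."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        h = self.hyperparameters
        if self.algorithm == "svm_rbf":
            if h.get("g", 1.0) <= 0 or h.get("c", 1.0) <= 0:
                raise ValueError("g and c must be positive")
            if h.get("j", 1) < 1:
                raise ValueError("cost factor j must be >= 1")
        if self.algorithm == "random_forest" and h.get("ntree", 1) < 1:
            raise ValueError("ntree must be >= 1")


@dataclass
class TrainedModel:
    """A fitted scorer plus the spec and feature scheme that produced it."""

    spec: ModelSpec
    estimator: object
    feature_scheme: str
    training_fingerprint: str
    seed: int

    def manifest(self) -> dict:
        return {
            "algorithm": self.spec.algorithm,
            "hyperparameters": self.spec.hyperparameters,
            "feature_scheme": self.feature_scheme,
            "seed": self.seed,
            "training_fingerprint": self.training_fingerprint,
            "sklearn_version": sklearn.__version__,
            "python_version": sys.version.split()[0],
        }


def _build_estimator(spec: ModelSpec, seed: int):
    h = spec.hyperparameters
    if spec.algorithm == "svm_rbf":
        return SVC(
            kernel="rbf",
            gamma=h.get("g", "scale"),
            C=h.get("c", 1.0),
            class_weight={1: h.get("j", 1), 0: 1},
            random_state=seed,
        )
    if spec.algorithm == "linear_margin":
        return SVC(
            kernel="linear",
            C=h.get("c", 1.0),
            class_weight={1: h.get("j", 1), 0: 1},
            random_state=seed,
        )
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=h.get("ntree", 20), random_state=seed
        )
    if spec.algorithm == "decision_tree":
        # WEKA-style m (min leaf); pruning confidence kept for provenance only
        return DecisionTreeClassifier(
            min_samples_leaf=h.get("m", 2), random_state=seed
        )
    if spec.algorithm == "naive_bayes":
        return GaussianNB()
    raise ValueError(spec.algorithm)


def _fingerprint(matrix: pd.DataFrame, labels: np.ndarray) -> str:
    hasher = hashlib.sha256()
    hasher.update(np.ascontiguousarray(matrix.to_numpy(dtype=float)).tobytes())
    hasher.update(np.ascontiguousarray(labels).tobytes())
    return hasher.hexdigest()[:16]


def train(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    spec: ModelSpec,
    seed: int = 0,
    feature_scheme: str = "unknown",
) -> TrainedModel:
    """Fit a scorer on a feature matrix (rows = peptides, labels 1/0)."""
    labels = np.asarray(labels, dtype=int)
    if len(matrix) != len(labels):
        raise ValueError("matrix rows and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs both classes present")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("training matrix contains NaN")
    est = _build_estimator(spec, seed)
    est.fit(X, labels)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_scheme=feature_scheme,
        training_fingerprint=_fingerprint(matrix, labels),
        seed=seed,
    )


def predict_scores(model: TrainedModel, matrix: pd.DataFrame) -> np.ndarray:
    """Real-valued scores, higher = more neuropeptide-like.

    Margin learners return the signed decision-function margin; probabilistic
    learners return ``2*p(positive) - 1``.  Threshold 0 splits the classes by
    default in both cases.
    """
    X = matrix.to_numpy(dtype=float)
    if X.size and np.isnan(X).any():
        raise ValueError("prediction matrix contains NaN")
    if X.shape[0] == 0:
        return np.array([])
    est = model.estimator
    if hasattr(est, "decision_function"):
        scores = est.decision_function(X)
    else:
        scores = 2.0 * est.predict_proba(X)[:, 1] - 1.0
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite prediction scores")
    return scores


def classify_at_threshold(scores: Sequence[float], threshold: float) -> np.ndarray:
    """1 where score >= threshold, else 0 (monotone in the threshold)."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def grid_search(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    algorithm: str,
    grid: Optional[dict[str, list]] = None,
    folds: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive hyperparameter search scored by five-fold CV.

    Every grid point is evaluated with :func:`neuropep.metrics.cross_validate`
    on the given fold assignment; the winner maximizes mean CV accuracy, ties
    broken by higher mean MCC, then by smaller ``c``.  Returns the best spec
    and the per-point CV summary table.
    """
    if folds is None:
        raise ValueError("grid_search requires a fold assignment")
    if grid is None:
        if algorithm != "svm_rbf":
            raise ValueError(f"no default grid for {algorithm!r}; pass one")
        grid = DEFAULT_SVM_GRID
    names = list(grid)
    if not names or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")

    combos = [{}]
    for name in names:
        combos = [dict(c, **{name: v}) for c in combos for v in grid[name]]

    rows = []
    for params in combos:
        spec = ModelSpec(algorithm, params)
        mean, _, _ = cross_validate(matrix, labels, folds, spec, seed=seed)
        rows.append({**params, "cv_acc": mean.acc, "cv_mcc": mean.mcc})
    summary = pd.DataFrame(rows)
    ranked = summary.sort_values(
        by=["cv_acc", "cv_mcc", "c"] if "c" in summary else ["cv_acc", "cv_mcc"],
        ascending=[False, False, True] if "c" in summary else [False, False],
        kind="stable",
    )
    best_params = {k: ranked.iloc[0][k] for k in names}
    # undo pandas float upcasting for integer-valued hyperparameters
    for k, v in best_params.items():
        if float(v).is_integer() and all(
            isinstance(g, (int, np.integer)) for g in grid[k]
        ):
            best_params[k] = int(v)
        else:
            best_params[k] = float(v)
    return ModelSpec(algorithm, best_params), summary


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model with an embedded JSON manifest."""
    payload = {"manifest": json.dumps(model.manifest()), "model": model}
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    return payload["model"]
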
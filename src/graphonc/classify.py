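"""Multi-class classifiers over feature matrices, with probabilistic scoring.

Four algorithms, configured as in the experimental setup: random forest with 500
trees, Gaussian naive Bayes with defaults, L2-regularized logistic regression,
and a C-classification SVM with a linear kernel (Platt-calibrated so that every
algorithm emits class probabilities).  Scores are one row per patient over the
training class order, rows summing to 1.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureMatrix


class Algorithm(str, Enum):
    RANDOM_FOREST = "random_forest"
    NAIVE_BAYES = "naive_bayes"
    LOGISTIC_REGRESSION = "logistic_regression"
    LINEAR_SVM = "linear_svm"


@dataclass(frozen=True)
class ClassifierSpec:
    algorithm: Algorithm = Algorithm.RANDOM_FOREST
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class ScoreMatrix:
    """Patients x classes probability matrix; rows sum to 1."""

    patient_ids: tuple[str, ...]
    class_order: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.patient_ids), len(self.class_order)):
            raise ValueError("score matrix shape mismatch")
        if self.scores.size and (
            self.scores.min() < -1e-9 or self.scores.max() > 1 + 1e-9
        ):
            raise ValueError("scores outside [0, 1]")
        if self.scores.size and not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("score rows do not sum to 1")

    def column(self, cls: str) -> np.ndarray:
        return self.scores[:, self.class_order.index(cls)]


def _build_estimator(spec: ClassifierSpec):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC

    hp = dict(spec.hyperparameters)
    if spec.algorithm is Algorithm.RANDOM_FOREST:
        hp.setdefault("n_estimators", 500)
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.algorithm is Algorithm.NAIVE_BAYES:
        return GaussianNB(**hp)
    if spec.algorithm is Algorithm.LOGISTIC_REGRESSION:
        hp.setdefault("penalty", "l2")
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.algorithm is Algorithm.LINEAR_SVM:
        hp.setdefault("kernel", "linear")
        hp.setdefault("probability", True)
        return SVC(random_state=spec.seed, **hp)
    raise ValueError(f"unknown algorithm {spec.algorithm}")


@dataclass
class TrainedModel:
    """A fitted estimator plus the feature-name manifest it was trained with.

    Columns that were constant in the training data are excluded from the fit
    (they carry no information and would only perturb the estimator's RNG
    stream); the manifest still lists them, and scoring masks them out, so
    adding a constant column leaves predictions bit-identical.
    """

    estimator: object
    feature_names: tuple[str, ...]
    class_order: tuple[str, ...]
    spec: ClassifierSpec
    active_columns: tuple[int, ...] = ()

    def predict_scores(self, matrix: FeatureMatrix) -> ScoreMatrix:
        """Score a feature matrix; columns must match training columns exactly."""
        if matrix.feature_names != self.feature_names:
            missing = set(self.feature_names) - set(matrix.feature_names)
            extra = set(matrix.feature_names) - set(self.feature_names)
            raise ValueError(
                f"feature columns do not match training manifest "
                f"(missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]}, "
                f"order_mismatch={not missing and not extra})"
            )
        return ScoreMatrix(
            matrix.patient_ids,
            self.class_order,
            self.score_array(matrix.values),
        )

    def score_array(self, X: np.ndarray) -> np.ndarray:
        """Raw probability scoring of a values array (columns as in training)."""
        X = np.asarray(X, dtype=float)
        if self.active_columns:
            X = X[:, list(self.active_columns)]
        proba = self.estimator.predict_proba(X)
        return proba / proba.sum(axis=1, keepdims=True)

    def save(self, path: str | Path) -> None:
        with Path(path).open("wb") as fh:
            pickle.dump(
                {
                    "version": 1,
                    "estimator": self.estimator,
                    "feature_names": self.feature_names,
                    "class_order": self.class_order,
                    "spec": self.spec,
                    "active_columns": self.active_columns,
                },
                fh,
            )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with Path(path).open("rb") as fh:
            blob = pickle.load(fh)
        if blob.get("version") != 1:
            raise ValueError(f"unsupported model file version {blob.get('version')}")
        return cls(
            blob["estimator"],
            blob["feature_names"],
            blob["class_order"],
            blob["spec"],
            blob.get("active_columns", ()),
        )


def train_classifier(
    matrix: FeatureMatrix,
    labels: Mapping[str, str] | Sequence[str],
    spec: ClassifierSpec = ClassifierSpec(),
) -> TrainedModel:
    """Fit the configured classifier; reproducible given ``spec.seed``.

    Raises on a single-class training set and on non-finite feature values.
    """
    if isinstance(labels, Mapping):
        y = np.asarray([labels[p] for p in matrix.patient_ids])
    else:
        y = np.asarray(labels)
        if y.shape[0] != len(matrix.patient_ids):
            raise ValueError("labels length does not match matrix rows")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"training set has a single class {classes.tolist()}")
    if not np.isfinite(matrix.values).all():
        raise ValueError("feature matrix contains non-finite values")
    active = tuple(np.flatnonzero(np.ptp(matrix.values, axis=0) > 0).tolist())
    if not active:
        raise ValueError("all feature columns are constant")
    est = _build_estimator(spec)
    est.fit(matrix.values[:, list(active)], y)
    return TrainedModel(est, matrix.feature_names, tuple(est.classes_), spec, active)
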
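"""Binary at-risk classifier: C-support vector classification, polynomial kernel.

The classifier contract is deliberately small — ``train`` returns an opaque
fitted model, ``decision_scores`` returns one real score per subject with
higher meaning more at-risk, and the hard at-risk call is ``score >= 0`` —
so any margin classifier can stand behind it.  The default realization is
scikit-learn's C-SVC with a polynomial kernel.

Hyperparameters default to the common library defaults for polynomial C-SVC
(degree 3, C = 1, gamma = 1/n_features, coef0 = 0); all are overridable.
Because the two-class decision function of an SVM has an arbitrary sign, the
score orientation is calibrated after training: if the training-set AUC of
the raw decision values is below 0.5, scores are negated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .metrics import auc


@dataclass
class ClassifierParams:
    kernel: str = "poly"
    degree: int = 3
    cost_c: float = 1.0
    gamma: float | str = "auto"  # "auto" = 1/n_features
    coef0: float = 0.0
    class_weight: str | None = None  # None or "balanced"
    seed: int = 0

    def validate(self) -> None:
        if self.kernel != "poly":
            raise ValueError(f"only the polynomial kernel is supported, got {self.kernel!r}")
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")
        if self.cost_c <= 0:
            raise ValueError(f"cost_c must be > 0, got {self.cost_c}")
        if self.class_weight not in (None, "balanced"):
            raise ValueError("class_weight must be None or 'balanced'")

    def make_estimator(self) -> SVC:
        self.validate()
        return SVC(
            kernel="poly",
            degree=self.degree,
            C=self.cost_c,
            gamma=self.gamma,
            coef0=self.coef0,
            class_weight=self.class_weight,
            random_state=self.seed,
        )


@dataclass
class TrainedModel:
    """A fitted classifier bound to an ordered feature list.

    ``orientation`` is +1 or -1 and fixes the decision scores so that higher
    always means more at-risk.
    """

    estimator: SVC
    feature_names: tuple[str, ...]
    orientation: int
    variant: str | None = None


def fit_oriented(X: np.ndarray, y: np.ndarray, params: ClassifierParams):
    """Fit the SVC and resolve the sign of its decision function.

    Returns ``(estimator, orientation)``; internal fast path shared by
    :func:`train` and the cross-validation engine.
    """
    est = params.make_estimator()
    est.fit(X, y)
    raw = est.decision_function(X)
    orientation = 1
    if len(np.unique(raw)) > 1 and auc(raw, y) < 0.5:
        orientation = -1
    return est, orientation


def train(X: pd.DataFrame, y, params: ClassifierParams | None = None) -> TrainedModel:
    """Train on a feature-selected matrix; deterministic given inputs."""
    params = params or ClassifierParams()
    yb = np.asarray(y).astype(int)
    classes, counts = np.unique(yb, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training outcome has a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    est, orientation = fit_oriented(X.to_numpy(dtype=float), yb, params)
    return TrainedModel(
        estimator=est, feature_names=tuple(X.columns), orientation=orientation
    )


def _check_features(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    have = set(X.columns)
    want = set(model.feature_names)
    missing = sorted(want - have)
    extra = sorted(have - want)
    if missing or extra:
        raise ValueError(
            f"feature mismatch: missing {missing or 'none'}, extra {extra or 'none'}"
        )
    return X[list(model.feature_names)].to_numpy(dtype=float)


def decision_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Oriented decision values; ``score >= 0`` reproduces the hard call."""
    values = _check_features(model, X)
    return model.orientation * model.estimator.decision_function(values)


def predict(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Hard at-risk calls from the native score cutoff of zero."""
    return decision_scores(model, X) >= 0.0


@dataclass
class CentroidClassifierParams:
    """Trivial margin classifier (difference of distances to class centroids).

    Exists to demonstrate that the train/decision_scores contract is
    implementation-agnostic; not used by the pipeline.
    """

    seed: int = 0

    def make_estimator(self):
        return _CentroidEstimator()

    def validate(self) -> None:  # same duck type as ClassifierParams
        pass


class _CentroidEstimator:
    def fit(self, X, y):
        self.mu1_ = X[y == 1].mean(axis=0)
        self.mu0_ = X[y == 0].mean(axis=0)
        return self

    def decision_function(self, X):
        d0 = np.linalg.norm(X - self.mu0_, axis=1)
        d1 = np.linalg.norm(X - self.mu1_, axis=1)
        return d0 - d1
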
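"""Treatment-effect evaluation: cross-validated logistic classification of
POD vs non-POD fraction features, prediction on a treated group, and the
POD incidence.

The classifier is logistic regression on the selected-movement fraction
features.  Its regularization strength is chosen by minimizing stratified
5-fold cross-validation error over 30 log-spaced candidate strengths; the
best-so-far error across candidates forms the minimum-classification-error
curve.  The chosen model then labels a treated group, and the incidence is
the percentage of treated animals labelled POD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

POD_LABEL = "POD"
NONPOD_LABEL = "nonPOD"


@dataclass
class ClassifierReport:
    """Cross-validation summary and the fitted final model."""

    chosen_c: float
    cv_errors: np.ndarray  # per candidate configuration
    best_so_far: np.ndarray  # running minimum (the error curve)
    confusions: list[np.ndarray]  # per-fold 2x2 matrices for the chosen C
    model: LogisticRegression
    classes: tuple[str, ...]
    folds: int
    seed: int

    @property
    def cv_error(self) -> float:
        """Minimum cross-validation error across candidates."""
        return float(self.best_so_far[-1])

    @property
    def coefficients(self) -> np.ndarray:
        return self.model.coef_[0]


@dataclass(frozen=True)
class IncidenceResult:
    """POD incidence of a labelled group, in percent."""

    n_total: int
    n_pod: int
    labels: tuple[str, ...]

    @property
    def incidence(self) -> float:
        return 100.0 * self.n_pod / self.n_total


def _cv_error(
    X: np.ndarray, y: np.ndarray, c: float, folds: int, seed: int,
    collect_confusions: bool = False,
) -> tuple[float, list[np.ndarray]]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = 0
    confusions: list[np.ndarray] = []
    for train, test in skf.split(X, y):
        clf = LogisticRegression(C=c, max_iter=5000)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        errors += int((pred != y[test]).sum())
        if collect_confusions:
            confusions.append(confusion_matrix(y[test], pred, labels=np.unique(y)))
    return errors / X.shape[0], confusions


def train_classifier(
    X_train: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    folds: int = 5,
    iterations: int = 30,
    seed: int = 0,
) -> ClassifierReport:
    """Logistic regression with CV-selected regularization strength.

    ``iterations`` log-spaced inverse-regularization candidates (C in
    [1e-4, 1e4]) are evaluated by stratified ``folds``-fold CV error;
    deterministic under ``seed`` (which fixes the fold shuffling).
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training needs both classes present")
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")
    candidates = np.logspace(-4, 4, iterations)
    cv_errors = np.array([
        _cv_error(X, y, c, folds, seed)[0] for c in candidates
    ])
    best_so_far = np.minimum.accumulate(cv_errors)
    chosen = int(np.argmin(cv_errors))
    _, confusions = _cv_error(
        X, y, candidates[chosen], folds, seed, collect_confusions=True
    )
    model = LogisticRegression(C=candidates[chosen], max_iter=5000)
    model.fit(X, y)
    return ClassifierReport(
        chosen_c=float(candidates[chosen]),
        cv_errors=cv_errors,
        best_so_far=best_so_far,
        confusions=confusions,
        model=model,
        classes=tuple(str(c) for c in classes),
        folds=folds,
        seed=seed,
    )


def predict_and_incidence(
    report: ClassifierReport | LogisticRegression,
    X_new: np.ndarray,
    pod_label: str = POD_LABEL,
) -> IncidenceResult:
    """Label new samples with the trained model and compute POD incidence."""
    model = report.model if isinstance(report, ClassifierReport) else report
    X = np.asarray(X_new, dtype=float)
    if X.size == 0:
        raise ValueError("X_new must be non-empty")
    if X.ndim != 2 or X.shape[1] != model.coef_.shape[1]:
        raise ValueError(
            f"feature-dimension mismatch: model expects {model.coef_.shape[1]}, "
            f"got {X.shape[1] if X.ndim == 2 else 'non-2D input'}"
        )
    pred = model.predict(X)
    n_pod = int((pred == pod_label).sum())
    return IncidenceResult(
        n_total=X.shape[0], n_pod=n_pod, labels=tuple(str(p) for p in pred)
    )
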
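"""Concussion prediction: logistic regression with leave-one-out CV.

The outcome is binary (concussion / no concussion), so concussion
likelihood is modeled with logistic regression.  Model quality is
estimated with leave-one-out cross-validation (LOOCV): each case is
predicted by a model trained on all other cases, and accuracy, sensitivity
and specificity are computed at a 0.5 threshold on the pooled out-of-fold
probabilities, alongside the pooled testing AUC and the mean training-fold
AUC.  The number of predictors is capped by the events-per-variable rule:
at 5 events per predictor, 20 concussive events allow at most 4 predictors.

Fits go through scikit-learn's LogisticRegression.  Predictors are
standardized internally and coefficients are reported on the original
scale.  An unpenalized fit is attempted first; if it fails to converge or
shows the runaway coefficients characteristic of complete separation
(common in small, well-separated impact datasets), the model is refit with
a small ridge penalty (1e-4 on standardized predictors) and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .lesion import NodeImportance
from .strain import KINEMATIC_FIELDS, ImpactCase

EPV = 5  # events-per-predictor-variable rule
SEPARATION_RIDGE = 1e-4
_SEPARATION_COEF_LIMIT = 30.0  # |beta| on standardized scale ~ odds ratio e^30


class RiskModelError(ValueError):
    """Raised for degenerate outcomes or invalid predictor sets."""


class SeparationWarning(UserWarning):
    """Emitted when an unpenalized fit is replaced by a ridge-penalized one."""


@dataclass(frozen=True)
class LogisticModel:
    """Fitted logistic regression, coefficients on the original scale."""

    coefficients: np.ndarray
    intercept: float
    converged: bool
    n_iterations: int
    regularization: float
    separation_fallback: bool = False

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = X @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


@dataclass(frozen=True)
class CVReport:
    """One row of a cross-validated prediction table for a predictor set."""

    predictor_set: tuple[str, ...]
    accuracy: float
    sensitivity: float
    specificity: float
    auc_testing: float
    auc_training_mean: float
    oof_probabilities: np.ndarray
    n_degenerate_folds: int = 0

    def as_dict(self) -> dict:
        return {
            "predictors": list(self.predictor_set),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc_testing": self.auc_testing,
            "auc_training_mean": self.auc_training_mean,
            "n_degenerate_folds": self.n_degenerate_folds,
        }


def epv_cap(n_events: int, epv: int = EPV) -> int:
    """Maximum predictor count under the events-per-variable rule."""
    if n_events < epv:
        raise RiskModelError(
            f"{n_events} events cannot support any predictor at {epv} events per variable"
        )
    return n_events // epv


def _validate_xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and np.asarray(y).size > 1:
        X = X.T
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] != y.size:
        raise RiskModelError(f"{X.shape[0]} rows of X for {y.size} outcomes")
    if set(np.unique(y)) - {0, 1}:
        raise RiskModelError("outcomes must be binary 0/1")
    return X, y


def fit_logistic(
    X: np.ndarray, y: np.ndarray, regularization: float = 0.0, max_iter: int = 500
) -> LogisticModel:
    """Maximum-likelihood (optionally ridge-penalized) logistic fit.

    ``regularization`` is the ridge strength applied to standardized
    coefficients; 0 requests the unpenalized MLE with automatic fallback to
    a minimal ridge (with a SeparationWarning) if the likelihood diverges.
    """
    X, y = _validate_xy(X, y)
    if len(set(y)) < 2:
        raise RiskModelError("both outcome classes must be present")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if np.any(degenerate) and regularization == 0:
        raise RiskModelError(
            "zero-variance predictor requires regularization > 0 "
            f"(columns {np.flatnonzero(degenerate).tolist()})"
        )
    sd_safe = np.where(degenerate, 1.0, sd)
    Z = (X - mu) / sd_safe

    def _fit(reg):
        C = 1.0 / reg if reg > 0 else np.inf  # C=inf -> unpenalized MLE
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Z, y)
        n_iter = int(np.max(clf.n_iter_))
        return clf, n_iter, n_iter < max_iter

    clf, n_iter, converged = _fit(regularization)
    fallback = False
    if regularization == 0 and (
        not converged or np.max(np.abs(clf.coef_)) > _SEPARATION_COEF_LIMIT
    ):
        warnings.warn(
            "unpenalized logistic fit diverged (likely complete separation); "
            f"refitting with ridge {SEPARATION_RIDGE}",
            SeparationWarning,
            stacklevel=2,
        )
        regularization = SEPARATION_RIDGE
        clf, n_iter, converged = _fit(regularization)
        fallback = True
    beta_std = clf.coef_.ravel()
    beta = beta_std / sd_safe
    intercept = float(clf.intercept_[0] - np.sum(beta_std * mu / sd_safe))
    return LogisticModel(beta, intercept, converged, n_iter, regularization, fallback)


def auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """AUC via the Mann-Whitney formulation with midrank tie handling.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) over all
    positive/negative case pairs.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise RiskModelError("AUC undefined with a single outcome class")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    regularization: float = 0.0,
    predictor_names: Sequence[str] | None = None,
) -> CVReport:
    """Leave-one-out cross-validated logistic prediction report.

    Folds whose training set contains a single class fall back to
    predicting the training class rate; they are counted, never fatal, so a
    53-fold LOOCV always completes.  Training-fold AUCs from degenerate
    folds are excluded from the training mean.

    ``auc_testing`` is computed once from the pooled out-of-fold
    probabilities.  Beware its behavior on *uninformative* predictors:
    holding out a positive case lowers its training fold's prevalence and
    coefficient pull, hence its own predicted probability, by O(1/N) — so
    the pooled ROC of a useless predictor sits well below 0.5 rather than
    at it (a documented artifact of pooling leave-one-out scores).  With
    informative predictors, as in this analysis, the artifact is
    negligible next to the signal.
    """
    X, y = _validate_xy(X, y)
    n = y.size
    if n < 3:
        raise RiskModelError("LOOCV needs at least 3 cases")
    if len(set(y)) < 2:
        raise RiskModelError("both outcome classes must be present")
    oof = np.empty(n)
    fold_prevalence = np.empty(n)
    train_aucs = []
    n_degenerate = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            X_tr, y_tr = X[mask], y[mask]
            fold_prevalence[i] = float(y_tr.mean())
            if len(set(y_tr)) < 2:
                oof[i] = fold_prevalence[i]
                n_degenerate += 1
                continue
            try:
                model = fit_logistic(X_tr, y_tr, regularization)
            except RiskModelError:
                # zero-variance predictor inside the fold: class-rate fallback
                oof[i] = fold_prevalence[i]
                n_degenerate += 1
                continue
            oof[i] = float(model.predict_proba(X[i : i + 1])[0])
            train_aucs.append(auc(model.predict_proba(X_tr), y_tr))
    predicted = oof >= 0.5
    tp = int(np.sum(predicted & (y == 1)))
    tn = int(np.sum(~predicted & (y == 0)))
    n_pos = int(y.sum())
    n_neg = n - n_pos
    names = tuple(predictor_names) if predictor_names is not None else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    return CVReport(
        predictor_set=names,
        accuracy=(tp + tn) / n,
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        auc_testing=auc(oof, y),
        auc_training_mean=float(np.mean(train_aucs)) if train_aucs else float("nan"),
        oof_probabilities=oof,
        n_degenerate_folds=n_degenerate,
    )


def _case_matrix(cases: Sequence[ImpactCase], columns: Sequence[str]) -> np.ndarray:
    cols = []
    for name in columns:
        if name.startswith("rmps["):
            rid = int(name[5:-1])
            cols.append([c.rmps[rid] for c in cases])
        else:
            cols.append([getattr(c, name) for c in cases])
    return np.column_stack(cols)


def _outcomes(cases: Sequence[ImpactCase]) -> np.ndarray:
    return np.array([1 if c.is_concussive else 0 for c in cases], dtype=int)


def evaluate_predictor_sets(
    cases: Sequence[ImpactCase],
    ranking: NodeImportance,
    max_k: int = 4,
    regularization: float = 0.0,
    include_baselines: bool = True,
) -> list[CVReport]:
    """LOOCV reports for incremental top-k rMPS predictor sets.

    Builds, for k = 1..max_k, the multivariate model whose predictors are
    the rMPS of the top-k regions of ``ranking`` (added strictly in rank
    order), plus — when ``include_baselines`` — univariate models for each
    of the four kinematic peaks and MPS95.  ``max_k`` may not exceed the
    events-per-variable cap (n_events // 5).
    """
    y = _outcomes(cases)
    cap = epv_cap(int(y.sum()))
    if max_k > cap:
        raise RiskModelError(
            f"max_k={max_k} exceeds the events-per-variable cap of {cap} "
            f"({int(y.sum())} events at {EPV} events per predictor)"
        )
    reports = []
    if include_baselines:
        for name in KINEMATIC_FIELDS + ("mps95",):
            X = _case_matrix(cases, [name])
            reports.append(loocv(X, y, regularization, [name]))
    top_regions = ranking.top(max_k)
    for k in range(1, max_k + 1):
        names = [f"rmps[{rid}]" for rid in top_regions[:k]]
        X = _case_matrix(cases, names)
        reports.append(loocv(X, y, regularization, names))
    return reports


@dataclass(frozen=True)
class PerSubjectSummary:
    """Spread of LOOCV performance across individual brain architectures."""

    reports: tuple[CVReport, ...]
    accuracy_min: float
    accuracy_max: float
    accuracy_mean: float

    def as_dict(self) -> dict:
        return {
            "accuracy_min": self.accuracy_min,
            "accuracy_max": self.accuracy_max,
            "accuracy_mean": self.accuracy_mean,
            "per_subject": [r.as_dict() for r in self.reports],
        }


def per_subject_evaluation(
    cases: Sequence[ImpactCase],
    subject_rankings: Sequence[NodeImportance],
    k: int,
    regularization: float = 0.0,
) -> PerSubjectSummary:
    """Evaluate the top-k predictor set under each subject's own ranking.

    Quantifies how much predictive performance depends on the individual
    connectome used to define region importance.
    """
    y = _outcomes(cases)
    cap = epv_cap(int(y.sum()))
    if k > cap:
        raise RiskModelError(f"k={k} exceeds the events-per-variable cap of {cap}")
    reports = []
    for ranking in subject_rankings:
        names = [f"rmps[{rid}]" for rid in ranking.top(k)]
        X = _case_matrix(cases, names)
        reports.append(loocv(X, y, regularization, names))
    accs = [r.accuracy for r in reports]
    lo, hi = float(min(accs)), float(max(accs))
    mean = min(max(float(np.mean(accs)), lo), hi)  # guard 1-ulp overshoot
    return PerSubjectSummary(tuple(reports), lo, hi, mean)
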
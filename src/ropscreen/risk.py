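"""Logistic ROP risk model, IRLS fitting, and ROC analysis.

The probability model behind the screening rule is a logistic regression of
the ROP outcome on two predictors measured by the end of the third week of
life: serum IGF1 (ng/ml) and a binary neonatal-sepsis indicator.  The original
probability-curve coefficients were never published, so this module provides
(a) a generic maximum-likelihood fit via iteratively reweighted least squares
with separation diagnostics, and (b) a reconstructed reference parameter set
(see :mod:`ropscreen.defaults`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (logit re-exported for calibration)

__all__ = [
    "LogisticRiskModel",
    "ROCCurve",
    "IRLSLogisticRegression",
    "PerfectSeparationWarning",
    "fit_logistic",
    "predict_probability",
    "igf1_threshold_classify",
    "roc_curve",
]


class PerfectSeparationWarning(UserWarning):
    """Raised as a warning when IRLS detects (quasi-)complete separation."""


@dataclass(frozen=True)
class LogisticRiskModel:
    """P(ROP) = expit(intercept + beta_igf1 * IGF1_3w + beta_sepsis * sepsis).

    Coefficients are on the log-odds scale: ``beta_igf1`` per ng/ml of week-3
    IGF1, ``beta_sepsis`` for sepsis diagnosed within the first 3 weeks.
    """

    intercept: float
    beta_igf1: float
    beta_sepsis: float
    converged: bool = True
    n_iter: int = 0
    loglik: float = math.nan
    se: tuple[float, float, float] | None = None
    outcome_def: str = "any_rop"
    fitted_on_n: int | None = None
    separation: bool = False

    def __post_init__(self) -> None:
        if self.converged and not all(
            math.isfinite(v) for v in (self.intercept, self.beta_igf1, self.beta_sepsis)
        ):
            raise ValueError("converged model requires finite coefficients")

    def linear_predictor(self, igf1_w3, sepsis_w3):
        igf1 = np.asarray(igf1_w3, dtype=float)
        sepsis = np.asarray(sepsis_w3, dtype=float)
        return self.intercept + self.beta_igf1 * igf1 + self.beta_sepsis * sepsis

    def to_dict(self) -> dict:
        d = asdict(self)
        d["se"] = list(self.se) if self.se is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticRiskModel":
        d = dict(d)
        if d.get("se") is not None:
            d["se"] = tuple(d["se"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "LogisticRiskModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def predict_probability(model: LogisticRiskModel, igf1_w3, sepsis_w3):
    """Predicted ROP probability, strictly inside (0, 1).

    Accepts scalars or arrays; scalar inputs return a float.
    """
    if not model.converged:
        raise ValueError("risk model did not converge; refusing to predict")
    igf1 = np.asarray(igf1_w3, dtype=float)
    sepsis = np.asarray(sepsis_w3, dtype=float)
    if not (np.all(np.isfinite(igf1)) and np.all(np.isfinite(sepsis))):
        raise ValueError("igf1_w3 and sepsis_w3 must be finite")
    if np.any(igf1 <= 0):
        raise ValueError("igf1_w3 must be > 0")
    p = expit(model.linear_predictor(igf1, sepsis))
    # keep probabilities strictly in (0,1) even in saturated tails
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)
    return float(p) if p.ndim == 0 else p


def igf1_threshold_classify(igf1_w3: float, cutoff: float = 30.0) -> str:
    """Single-biomarker discriminator: ``at_risk`` iff IGF1 < cutoff (strict).

    The week-3 IGF1 threshold of 30 ng/ml is the univariate screen from which
    the two-predictor probability model was later developed.
    """
    igf1 = float(igf1_w3)
    if not math.isfinite(igf1) or igf1 <= 0:
        raise ValueError("igf1_w3 must be finite and > 0")
    return "at_risk" if igf1 < cutoff else "not_at_risk"


class IRLSLogisticRegression:
    """Binary logistic regression fitted by iteratively reweighted least squares.

    scikit-learn style estimator: ``fit(X, y)`` then ``predict_proba``.
    Newton/IRLS from an all-zero start, with step-halving so the log-likelihood
    is non-decreasing across iterations, a tiny ridge jitter on the weighted
    normal equations for numerical safety, and a (quasi-)complete-separation
    diagnostic instead of silently diverging coefficients.

    Parameters
    ----------
    tol : float
        Convergence when the max absolute coefficient update falls below this.
    max_iter : int
        Iteration cap; hitting it leaves ``converged_ = False``.
    ridge : float
        Jitter added to the diagonal of X'WX before solving.
    fit_intercept : bool
        Prepend a constant column to the design matrix.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    converged_ : bool
    separation_ : bool
    n_iter_ : int
    loglik_ : float
    bse_ : ndarray — standard errors from the inverse Fisher information
    loglik_path_ : list of per-iteration log-likelihoods
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100,
                 ridge: float = 1e-8, fit_intercept: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge
        self.fit_intercept = fit_intercept

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_iter": self.max_iter,
                "ridge": self.ridge, "fit_intercept": self.fit_intercept}

    def set_params(self, **params) -> "IRLSLogisticRegression":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
        # numerically stable: -sum(log(1+exp(-(2y-1)*eta)))
        s = (2.0 * y - 1.0) * eta
        return -float(np.sum(np.logaddexp(0.0, -s)))

    def fit(self, X, y) -> "IRLSLogisticRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if y.shape != (n,):
            raise ValueError("X and y have incompatible shapes")
        classes = np.unique(y)
        if not np.all(np.isin(classes, (0.0, 1.0))):
            raise ValueError("y must be binary 0/1")
        if classes.size < 2:
            raise ValueError("outcome has a single class; cannot fit")
        if self.fit_intercept:
            X = np.column_stack([np.ones(n), X])
        d = X.shape[1]

        beta = np.zeros(d)
        eta = X @ beta
        ll = self._loglik(y, eta)
        self.loglik_path_ = [ll]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            # Newton step via weighted least squares on the working response
            z = eta + (y - mu) / w
            XtW = X.T * w
            A = XtW @ X + self.ridge * np.eye(d)
            beta_new = np.linalg.solve(A, XtW @ z)
            step = beta_new - beta
            # step-halving keeps the log-likelihood monotone
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new = self._loglik(y, X @ cand)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta_new = beta + scale * step
            eta = X @ beta_new
            ll_new = self._loglik(y, eta)
            delta = np.max(np.abs(beta_new - beta))
            beta = beta_new
            ll = ll_new
            self.loglik_path_.append(ll)
            if delta < self.tol:
                converged = True
                break

        mu = expit(eta)
        # (quasi-)complete separation: every record is predicted essentially
        # perfectly while the linear predictor runs away
        separated = bool(
            np.max(np.abs(eta)) > 30 and np.all(np.abs(y - mu) < 1e-3)
        ) or bool(not converged and np.all(np.abs(y - mu) < 1e-3))
        if separated:
            converged = False

        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (X.T * w) @ X
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            bse = np.full(d, np.nan)

        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.converged_ = converged
        self.separation_ = separated
        self.n_iter_ = it
        self.loglik_ = ll
        self.bse_ = bse
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0.0).astype(float)


def fit_logistic(cohort, outcome_def: str = "any_rop",
                 tol: float = 1e-8, max_iter: int = 100) -> LogisticRiskModel:
    """ML fit of the two-predictor ROP model on a cohort.

    ``outcome_def`` is ``any_rop`` (any ROP grade vs none) or
    ``proliferative_only``.  Requires at least 10 records and both outcome
    classes present; perfect separation is flagged on the returned model
    (``separation=True, converged=False``), never returned as silent garbage.
    """
    if outcome_def not in ("any_rop", "proliferative_only"):
        raise ValueError(f"unknown outcome_def {outcome_def!r}")
    frame = cohort.frame if hasattr(cohort, "frame") else cohort
    if len(frame) < 10:
        raise ValueError("need >= 10 records to fit the risk model")
    if outcome_def == "any_rop":
        y = (frame["rop_grade"] != "none").to_numpy(dtype=float)
    else:
        y = (frame["rop_grade"] == "proliferative").to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome has a single class; cannot fit")
    X = frame[["igf1_w3", "sepsis_w3"]].to_numpy(dtype=float)
    est = IRLSLogisticRegression(tol=tol, max_iter=max_iter).fit(X, y)
    return LogisticRiskModel(
        intercept=est.intercept_,
        beta_igf1=float(est.coef_[0]),
        beta_sepsis=float(est.coef_[1]),
        converged=est.converged_,
        n_iter=est.n_iter_,
        loglik=est.loglik_,
        se=tuple(float(s) for s in est.bse_),
        outcome_def=outcome_def,
        fitted_on_n=len(frame),
        separation=est.separation_,
    )


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve with trapezoidal AUC.

    ``thresholds[i]`` is the score cut-off at which (fpr[i], tpr[i]) is
    attained by the rule "positive iff score >= threshold"; the leading
    (0, 0) point carries threshold +inf.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float = field(default=math.nan)

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc outside [0, 1]")


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Empirical ROC over all distinct score thresholds.

    Tied scores are grouped at a single threshold, so the trapezoidal AUC
    equals the Mann-Whitney U statistic (positives vs negatives, ties counted
    half) divided by n_pos * n_neg.
    """
    s = np.asarray(scores, dtype=float)
    yv = np.asarray(labels)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    yv = yv.astype(float)
    if not np.all(np.isin(np.unique(yv), (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    n_pos = int(np.sum(yv == 1.0))
    n_neg = int(np.sum(yv == 0.0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = yv[order]
    # group tied scores: cumulative counts at the last index of each tie block
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[idx]
    fp = np.cumsum(1.0 - y_sorted)[idx]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)
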
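"""Backward-stepwise logistic regression for transition biomarkers.

Candidate predictors are baseline M-values of validated CpGs, standardized
to unit SD so every odds ratio reads "per 1 SD of baseline M".  The core
fit is maximum likelihood by iteratively reweighted least squares with an
optional ridge penalty (intercept unpenalized) as the escape hatch for the
perfect separation that small n with strong predictors produces; Wald
standard errors come from the inverse (penalized) observed information.
Backward elimination drops the weakest term — largest Wald p, or the
removal with the best AIC improvement — until every retained term meets
the stay criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "SeparationError",
    "LogisticFit",
    "BiomarkerModel",
    "fit_logistic",
    "odds_ratio_ci",
    "backward_stepwise",
    "StepwiseLogisticRegression",
]


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation with an unpenalized fit."""


@dataclass
class LogisticFit:
    """Maximum-likelihood (optionally ridge-penalized) logistic fit."""

    terms: list[str]          # predictor names, intercept excluded
    intercept: float
    coef: np.ndarray          # per-predictor log odds
    se: np.ndarray            # Wald standard errors (intercept excluded)
    p_values: np.ndarray
    loglik: float
    aic: float
    penalty: float
    converged: bool

    def wald_table(self) -> pd.DataFrame:
        ors = np.exp(self.coef)
        z = stats.norm.ppf(0.975)
        return pd.DataFrame({
            "coef": self.coef,
            "se": self.se,
            "odds_ratio": ors,
            "ci_low": np.exp(self.coef - z * self.se),
            "ci_high": np.exp(self.coef + z * self.se),
            "p_value": self.p_values,
        }, index=self.terms)


def _irls(X: np.ndarray, y: np.ndarray, penalty: float,
          max_iter: int = 200, tol: float = 1e-10):
    """IRLS on the design with leading intercept column; ridge penalty on
    all non-intercept coefficients."""
    n, d = X.shape
    beta = np.zeros(d)
    pen = np.full(d, penalty)
    pen[0] = 0.0
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu) - pen * beta
        info = (X.T * w) @ X + np.diag(pen)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix; add a ridge penalty "
                "(penalty > 0) or reduce the candidate set") from exc
        # halve the step until the penalized log-likelihood does not decrease
        def pll(b):
            e = np.clip(X @ b, -35, 35)
            return float(y @ e - np.logaddexp(0.0, e).sum()
                         - 0.5 * (pen * b * b).sum())
        base = pll(beta)
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            if pll(cand) >= base - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        if float(np.max(np.abs(scale * step))) < tol * (1.0 + float(np.max(np.abs(beta)))):
            converged = True
            break
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X.T * w) @ X + np.diag(pen)
    if penalty == 0.0:
        # separation diagnostics: diverging coefficients or fitted
        # probabilities pinned at 0/1 for every observation
        if (not converged) or np.max(np.abs(beta[1:]), initial=0.0) > 25 or (
                d > 1 and np.all((mu < 1e-6) | (mu > 1 - 1e-6))):
            raise SeparationError(
                "perfect separation detected; refit with penalty > 0")
    cov = np.linalg.inv(info)
    loglik = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return beta, cov, loglik, converged


def fit_logistic(X, y, penalty: float = 0.0, terms: list[str] | None = None) -> LogisticFit:
    """Fit a logistic model (columns of ``X`` are the predictors; an
    intercept is always included).

    Raises
    ------
    ValueError
        If a predictor column is constant.
    SeparationError
        On perfect separation with ``penalty == 0``.
    """
    if isinstance(X, pd.DataFrame):
        terms = list(X.columns) if terms is None else terms
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        terms = terms or [f"x{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X and y have different lengths")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if X.shape[1] and np.any(X.std(axis=0) == 0):
        bad = [terms[i] for i in np.flatnonzero(X.std(axis=0) == 0)]
        raise ValueError(f"constant predictor(s): {bad}")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")

    design = np.column_stack([np.ones(len(y)), X])
    beta, cov, loglik, converged = _irls(design, y, penalty)
    se = np.sqrt(np.diag(cov))[1:]
    z = beta[1:] / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    k = design.shape[1]
    return LogisticFit(terms=terms, intercept=float(beta[0]),
                       coef=beta[1:].copy(), se=se, p_values=p,
                       loglik=loglik, aic=2.0 * k - 2.0 * loglik,
                       penalty=penalty, converged=converged)


def odds_ratio_ci(coefficient: float, se: float, level: float = 0.95
                  ) -> tuple[float, float, float]:
    """Odds ratio with the Wald interval on the log-odds scale."""
    if se <= 0:
        raise ValueError("se must be > 0")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    z = stats.norm.ppf((1.0 + level) / 2.0)
    or_ = math.exp(coefficient)
    return or_, math.exp(coefficient - z * se), math.exp(coefficient + z * se)


@dataclass
class BiomarkerModel:
    """Final stepwise model: predictors with per-SD odds ratios, 95% Wald
    CIs, p-values and the elimination trace."""

    predictors: list[str]
    coefficients: dict[str, float]
    odds_ratios: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    intercept: float
    elimination_trace: list[tuple[str, float]]
    covariates: list[str] = field(default_factory=list)
    penalty: float = 0.0
    criterion: str = "wald_p"
    alpha_stay: float = 0.05

    def to_dict(self) -> dict:
        d = asdict(self)
        d["elimination_trace"] = [[t, v] for t, v in self.elimination_trace]
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients,
            "odds_ratio": self.odds_ratios,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_values,
        }).loc[self.predictors]


class StepwiseLogisticRegression(BaseEstimator, ClassifierMixin):
    """Backward-stepwise logistic regression, sklearn classifier style.

    Parameters
    ----------
    alpha_stay : float
        Wald-p stay threshold (``criterion="wald_p"``).
    criterion : {"wald_p", "aic"}
        Elimination rule: drop the largest Wald p until all retained terms
        have p < alpha_stay, or drop whichever removal lowers AIC most
        until no removal improves AIC.
    penalty : float
        Ridge penalty on standardized coefficients (0 = plain ML; perfect
        separation then raises :class:`SeparationError`).
    covariates : sequence of str or None
        Columns forced into the model; never eliminated.
    standardize : bool
        Scale every predictor to zero mean / unit SD before fitting, so
        odds ratios are per 1 SD (default True).
    """

    def __init__(self, alpha_stay: float = 0.05, criterion: str = "wald_p",
                 penalty: float = 0.0, covariates=None, standardize: bool = True):
        self.alpha_stay = alpha_stay
        self.criterion = criterion
        self.penalty = penalty
        self.covariates = covariates
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y):
        if self.criterion not in ("wald_p", "aic"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        X = pd.DataFrame(X).copy()
        X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float).ravel()
        forced = [str(c) for c in (self.covariates or [])]
        missing = set(forced) - set(X.columns)
        if missing:
            raise ValueError(f"forced covariates absent from X: {sorted(missing)}")
        if X.shape[1] < 1:
            raise ValueError("at least one candidate predictor is required")

        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            if np.any(sd == 0):
                bad = list(X.columns[sd == 0])
                raise ValueError(f"constant predictor(s): {bad}")
            Xs = (X - mu) / sd
            self.center_, self.scale_ = mu, sd
        else:
            Xs = X
            self.center_ = pd.Series(0.0, index=X.columns)
            self.scale_ = pd.Series(1.0, index=X.columns)

        terms = list(X.columns)
        trace: list[tuple[str, float]] = []
        fit = fit_logistic(Xs[terms], y, penalty=self.penalty)
        while terms:
            droppable = [t for t in terms if t not in forced]
            if not droppable:
                break
            if self.criterion == "wald_p":
                pvals = dict(zip(fit.terms, fit.p_values))
                # worst term: largest p, ties broken by name ascending
                worst = sorted(droppable, key=lambda t: (-pvals[t], t))[0]
                if pvals[worst] < self.alpha_stay:
                    break
                trace.append((worst, float(pvals[worst])))
                terms = [t for t in terms if t != worst]
                fit = self._refit(Xs, y, terms)
            else:  # aic
                best_t, best_fit, best_aic = None, None, fit.aic
                for t in sorted(droppable):
                    cand = self._refit(Xs, y, [u for u in terms if u != t])
                    if cand.aic < best_aic - 1e-12:
                        best_t, best_fit, best_aic = t, cand, cand.aic
                if best_t is None:
                    break
                trace.append((best_t, float(best_aic)))
                terms = [t for t in terms if t != best_t]
                fit = best_fit

        self.fit_ = fit
        self.predictors_ = list(fit.terms)
        self.intercept_ = fit.intercept
        self.coef_ = fit.coef.copy()
        table = fit.wald_table()
        self.odds_ratios_ = table["odds_ratio"].to_dict()
        self.conf_int_ = table[["ci_low", "ci_high"]].copy()
        self.p_values_ = table["p_value"].to_dict()
        self.trace_ = trace
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.model_ = BiomarkerModel(
            predictors=self.predictors_,
            coefficients={t: float(c) for t, c in zip(fit.terms, fit.coef)},
            odds_ratios={t: float(v) for t, v in self.odds_ratios_.items()},
            ci_low=table["ci_low"].to_dict(),
            ci_high=table["ci_high"].to_dict(),
            p_values={t: float(v) for t, v in self.p_values_.items()},
            intercept=fit.intercept,
            elimination_trace=trace,
            covariates=forced,
            penalty=self.penalty,
            criterion=self.criterion,
            alpha_stay=self.alpha_stay,
        )
        return self

    def _refit(self, Xs: pd.DataFrame, y: np.ndarray, terms: list[str]) -> LogisticFit:
        if terms:
            return fit_logistic(Xs[terms], y, penalty=self.penalty)
        # intercept-only model remains a valid stepwise outcome
        n = len(y)
        p1 = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        ll = float(n * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1)))
        return LogisticFit(terms=[], intercept=math.log(p1 / (1 - p1)),
                           coef=np.empty(0), se=np.empty(0),
                           p_values=np.empty(0), loglik=ll, aic=2 - 2 * ll,
                           penalty=self.penalty, converged=True)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        Xs = (X[self.predictors_] - self.center_[self.predictors_]) / \
            self.scale_[self.predictors_] if self.predictors_ else None
        eta = np.full(len(X), self.intercept_)
        if self.predictors_:
            eta = eta + Xs.to_numpy(dtype=float) @ self.coef_
        return eta

    def predict_proba(self, X) -> np.ndarray:
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def backward_stepwise(X, y, alpha_stay: float = 0.05, criterion: str = "wald_p",
                      covariates=None, penalty: float = 0.0,
                      standardize: bool = True) -> BiomarkerModel:
    """Functional interface over :class:`StepwiseLogisticRegression`."""
    est = StepwiseLogisticRegression(alpha_stay=alpha_stay, criterion=criterion,
                                     penalty=penalty, covariates=covariates,
                                     standardize=standardize)
    est.fit(pd.DataFrame(X), y)
    return est.model_
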
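"""Maximum-likelihood logistic regression with offset support.

The fitter is plain Newton-Raphson/IRLS with a step-halving line search,
which gives direct control over the convergence contract (score tolerance),
offsets (needed by the calibration measures) and separation diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = ["StandardLogistic", "StandardFit", "fit_standard_logistic"]


def bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    """Sum of Bernoulli log-likelihood terms y*eta - log(1 + exp(eta))."""
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class StandardLogistic(BaseEstimator):
    """Standard (fixed-effects-only) logistic regression fitted by ML.

    Parameters
    ----------
    fit_intercept : include an intercept column (default True).
    max_iter : maximum Newton iterations.
    score_tol : converged when the maximum absolute score falls below this.
    loglik_tol : alternative stop on relative log-likelihood change.
    separation_lp : |linear predictor| beyond this at convergence flags
        (quasi-)complete separation in ``separation_``.

    Attributes
    ----------
    intercept_ : fitted intercept (log-odds); 0.0 when fit_intercept=False.
    coef_ : fitted predictor coefficients (log-odds ratios), shape (p,).
    params_ : full coefficient vector as fitted (intercept first if present).
    se_ : Wald standard errors aligned with ``params_``.
    loglik_ : maximized log-likelihood.
    converged_, n_iter_, separation_ : fit diagnostics.
    """

    def __init__(
        self,
        fit_intercept: bool = True,
        max_iter: int = 100,
        score_tol: float = 1e-8,
        loglik_tol: float = 1e-10,
        separation_lp: float = 30.0,
    ):
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.score_tol = score_tol
        self.loglik_tol = loglik_tol
        self.separation_lp = separation_lp

    def fit(self, X, y, offset=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size != 1:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        if X.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float).ravel()
        design = np.column_stack([np.ones(n), X]) if self.fit_intercept else X
        if design.shape[1] == 0:
            raise ValueError("empty design: no predictors and fit_intercept=False")
        if n <= design.shape[1] - 1:
            raise ValueError("need more observations than predictors")

        beta = np.zeros(design.shape[1])
        eta = design @ beta + offset
        ll = bernoulli_loglik(eta, y)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            p = expit(eta)
            score = design.T @ (y - p)
            if np.max(np.abs(score)) < self.score_tol:
                converged = True
                break
            w = p * (1.0 - p)
            info = design.T @ (design * w[:, None])
            step = np.linalg.solve(info, score)
            # step-halving: never accept a decrease in log-likelihood
            for _ in range(30):
                eta_new = design @ (beta + step) + offset
                ll_new = bernoulli_loglik(eta_new, y)
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            beta = beta + step
            eta = eta_new
            if abs(ll_new - ll) < self.loglik_tol * (abs(ll) + 1e-12):
                ll = ll_new
                p = expit(eta)
                converged = np.max(np.abs(design.T @ (y - p))) < np.sqrt(self.score_tol)
                break
            ll = ll_new

        p = expit(eta)
        info = design.T @ (design * (p * (1.0 - p))[:, None])
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(design.shape[1], np.nan)
        self.params_ = beta
        self.se_ = se
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.loglik_ = float(bernoulli_loglik(eta, y))
        self.n_iter_ = it
        # separation: runaway linear predictor, or an (almost) perfect fit
        self.separation_ = bool(
            np.max(np.abs(eta - offset)) > self.separation_lp
            or self.loglik_ > -1e-6 * n
        )
        self.converged_ = bool(converged and not self.separation_)
        return self

    def decision_function(self, X, offset=None):
        """Linear predictor alpha + X beta (+ offset)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.coef_.shape[0]}"
            )
        lp = self.intercept_ + X @ self.coef_
        if offset is not None:
            lp = lp + np.asarray(offset, dtype=float).ravel()
        return lp

    def predict_proba(self, X, offset=None):
        p = expit(self.decision_function(X, offset))
        return np.column_stack([1.0 - p, p])

    def predict(self, X, offset=None):
        return (self.decision_function(X, offset) > 0).astype(int)


@dataclass
class StandardFit:
    """Fitted-model container for the standard logistic model."""

    alpha: float
    beta: np.ndarray
    se: np.ndarray       # aligned with (alpha, beta)
    loglik: float
    converged: bool
    n_iter: int
    separation: bool
    model: StandardLogistic

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) Wald confidence limits for (alpha, beta...)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        est = np.concatenate([[self.alpha], self.beta])
        return np.column_stack([est - z * self.se, est + z * self.se])


def fit_standard_logistic(X, y, offset=None, **kwargs) -> StandardFit:
    """Fit a standard logistic regression; thin wrapper over StandardLogistic."""
    model = StandardLogistic(**kwargs).fit(X, y, offset=offset)
    return StandardFit(
        alpha=model.intercept_,
        beta=model.coef_,
        se=model.se_,
        loglik=model.loglik_,
        converged=model.converged_,
        n_iter=model.n_iter_,
        separation=model.separation_,
        model=model,
    )
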
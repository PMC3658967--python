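"""Logistic regression with normal random effects, fitted by maximum
marginal likelihood via adaptive Gauss-Hermite quadrature (AGQ).

Two model families are provided:

* :class:`RandomInterceptLogistic` — fixed effects plus one normal random
  intercept per cluster, the workhorse prediction model.  The marginal
  likelihood integrates each cluster's Bernoulli likelihood over the random
  intercept; the integral is approximated with quadrature nodes recentred at
  each cluster's posterior mode and rescaled by the posterior curvature
  (adaptive), which keeps few nodes accurate even for variances well above 1.
* mixed recalibration models (:func:`fit_mixed_calibration_large`,
  :func:`fit_mixed_calibration_slope`) — intercept-only with a random
  intercept and offset, or intercept+slope with independent random intercept
  and random slope (2-D product quadrature), used for within-cluster
  calibration assessment.

The variance parameters are optimized on the log-standard-deviation scale so
they stay non-negative; fits that pin the scale at the lower bound are
reported as boundary fits with variance 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, roots_hermite
from sklearn.base import BaseEstimator

from .glm import StandardLogistic, bernoulli_loglik

__all__ = [
    "RandomInterceptLogistic",
    "RandomInterceptFit",
    "MixedCalibrationFit",
    "fit_random_intercept_logistic",
    "fit_mixed_calibration_large",
    "fit_mixed_calibration_slope",
    "marginal_loglik",
]

_LOG_SIGMA_LO = -6.0  # sigma = e^-6: operationally a zero-variance boundary
_LOG_SIGMA_HI = 2.5

_LOG_2PI = np.log(2.0 * np.pi)


def _cluster_bernoulli(eta: np.ndarray, y: np.ndarray, cidx: np.ndarray, J: int) -> np.ndarray:
    """Per-cluster sums of Bernoulli log-likelihood terms."""
    return np.bincount(cidx, weights=y * eta - np.logaddexp(0.0, eta), minlength=J)


def _posterior_modes(
    fe: np.ndarray,
    y: np.ndarray,
    cidx: np.ndarray,
    J: int,
    sigma2: float,
    u0: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 60,
):
    """Damped Newton for the per-cluster posterior modes of the random
    intercept (all clusters in parallel).  Returns (modes, curvatures)."""
    u = u0.copy()

    def objective(u):
        eta = fe + u[cidx]
        return _cluster_bernoulli(eta, y, cidx, J) - u**2 / (2.0 * sigma2)

    obj = objective(u)
    for _ in range(max_iter):
        eta = fe + u[cidx]
        p = expit(eta)
        g = np.bincount(cidx, weights=y - p, minlength=J) - u / sigma2
        h = -np.bincount(cidx, weights=p * (1.0 - p), minlength=J) - 1.0 / sigma2
        step = np.clip(-g / h, -4.0, 4.0)
        if np.max(np.abs(step)) < tol:
            break
        for _ in range(25):
            obj_new = objective(u + step)
            worse = obj_new < obj - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
        u = u + step
        obj = obj_new
    eta = fe + u[cidx]
    p = expit(eta)
    h = -np.bincount(cidx, weights=p * (1.0 - p), minlength=J) - 1.0 / sigma2
    return u, -h  # curvature = -h > 0


def _agq_cluster_logliks(
    fe: np.ndarray,
    y: np.ndarray,
    cidx: np.ndarray,
    J: int,
    sigma: float,
    nodes: np.ndarray,
    logw: np.ndarray,
    u_mode: np.ndarray | None = None,
    adaptive: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster marginal log-likelihood contributions.

    Returns (loglik_per_cluster, posterior_modes).  With ``adaptive=False``
    the quadrature is centred at 0 with scale sigma (non-adaptive
    Gauss-Hermite), which serves as a refinement oracle at high node counts.
    """
    sigma2 = sigma * sigma
    if u_mode is None:
        u_mode = np.zeros(J)
    if adaptive:
        u_hat, curv = _posterior_modes(fe, y, cidx, J, sigma2, u_mode)
        tau2 = 1.0 / curv
    else:
        u_hat = np.zeros(J)
        tau2 = np.full(J, sigma2)
    scale = np.sqrt(2.0 * tau2)  # (J,)
    K = nodes.shape[0]
    terms = np.empty((K, J))
    for k in range(K):
        u_k = u_hat + scale * nodes[k]
        eta = fe + u_k[cidx]
        ll = _cluster_bernoulli(eta, y, cidx, J)
        log_phi = -0.5 * (_LOG_2PI + 2.0 * np.log(sigma) + u_k**2 / sigma2)
        terms[k] = logw[k] + nodes[k] ** 2 + ll + log_phi
    ll_j = np.log(scale) + logsumexp(terms, axis=0)
    return ll_j, u_hat


def marginal_loglik(
    X,
    y,
    groups,
    params: np.ndarray,
    sigma: float,
    offset=None,
    n_quad: int = 15,
    adaptive: bool = True,
) -> float:
    """Marginal log-likelihood of a random-intercept logistic model at given
    parameter values (params = intercept followed by coefficients).

    At sigma = 0 the integral degenerates and the standard logistic
    log-likelihood is returned exactly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    design = np.column_stack([np.ones(n), X])
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float).ravel()
    _, cidx = np.unique(np.asarray(groups), return_inverse=True)
    J = cidx.max() + 1
    fe = design @ np.asarray(params, dtype=float) + offset
    if sigma <= 0.0:
        return bernoulli_loglik(fe, y)
    t, w = roots_hermite(n_quad)
    ll_j, _ = _agq_cluster_logliks(
        fe, y, cidx, J, sigma, t, np.log(w), adaptive=adaptive
    )
    return float(ll_j.sum())


class RandomInterceptLogistic(BaseEstimator):
    """Logistic regression with a normal random intercept per cluster.

    Fitted by maximizing the marginal likelihood (adaptive Gauss-Hermite
    quadrature, ``n_quad`` nodes) over the fixed effects and log sigma.

    Parameters
    ----------
    n_quad : quadrature nodes (default 15).
    adaptive : recentre/rescale nodes at the cluster posterior modes.
    eb_method : "mode" (posterior mode, default) or "mean" (posterior mean)
        for the empirical-Bayes cluster predictions ``u0_``.
    separation_lp : fixed-effect linear-predictor magnitude flagged as
        separation.

    Attributes
    ----------
    intercept_, coef_ : fixed effects (log-odds scale).
    sigma2_u0_ : random-intercept variance; exactly 0.0 for boundary fits.
    u0_ : empirical-Bayes prediction per cluster, aligned with ``clusters_``.
    se_ : Wald SEs for (intercept, coef...); ``se_log_variance_`` for
        log(sigma2).
    loglik_ : maximized marginal log-likelihood.
    converged_, boundary_ : fit diagnostics.
    """

    def __init__(
        self,
        n_quad: int = 15,
        adaptive: bool = True,
        eb_method: str = "mode",
        max_iter: int = 200,
        separation_lp: float = 30.0,
        compute_se: bool = True,
    ):
        self.n_quad = n_quad
        self.adaptive = adaptive
        self.eb_method = eb_method
        self.max_iter = max_iter
        self.separation_lp = separation_lp
        self.compute_se = compute_se

    def fit(self, X, y, groups, offset=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        n = y.shape[0]
        if X.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float).ravel()
        clusters, cidx = np.unique(np.asarray(groups), return_inverse=True)
        J = clusters.shape[0]
        design = np.column_stack([np.ones(n), X])
        p = design.shape[1]
        t, w = roots_hermite(self.n_quad)
        logw = np.log(w)

        # warm start: standard logistic for the fixed effects
        start = StandardLogistic().fit(X, y, offset=offset) if X.shape[1] else \
            StandardLogistic().fit(np.empty((n, 0)), y, offset=offset)
        theta0 = np.concatenate([start.params_, [np.log(0.4)]])

        u_cache = {"u": np.zeros(J)}

        def negloglik(theta):
            gamma, s = theta[:p], theta[p]
            sigma = np.exp(s)
            fe = design @ gamma + offset
            ll_j, u_hat = _agq_cluster_logliks(
                fe, y, cidx, J, sigma, t, logw,
                u_mode=u_cache["u"], adaptive=self.adaptive,
            )
            if self.adaptive:
                u_cache["u"] = u_hat
            return -float(ll_j.sum())

        bounds = [(None, None)] * p + [(_LOG_SIGMA_LO, _LOG_SIGMA_HI)]
        res = minimize(
            negloglik,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": 1e-7},
        )
        gamma, s = res.x[:p], res.x[p]
        sigma = float(np.exp(s))
        boundary = s <= _LOG_SIGMA_LO + 1e-6
        fe = design @ gamma + offset

        if boundary:
            sigma2 = 0.0
            u_hat = np.zeros(J)
            loglik = bernoulli_loglik(fe, y)
        else:
            sigma2 = sigma * sigma
            ll_j, u_hat = _agq_cluster_logliks(
                fe, y, cidx, J, sigma, t, logw, u_mode=u_cache["u"]
            )
            loglik = float(ll_j.sum())
            if self.eb_method == "mean":
                u_hat = self._posterior_means(fe, y, cidx, J, sigma, t, w, u_hat)
            elif self.eb_method != "mode":
                raise ValueError(f"unknown eb_method {self.eb_method!r}")

        se = np.full(p, np.nan)
        se_logvar = np.nan
        if not self.compute_se:
            pass
        elif not boundary:
            H = _numerical_hessian(negloglik, res.x)
            try:
                cov = np.linalg.inv(H)
                d = np.diag(cov)
                if np.all(d[:p] > 0):
                    se = np.sqrt(d[:p])
                if d[p] > 0:
                    se_logvar = 2.0 * np.sqrt(d[p])  # log sigma2 = 2 log sigma
            except np.linalg.LinAlgError:
                pass
        else:
            se = StandardLogistic().fit(X, y, offset=offset).se_ if X.shape[1] else \
                StandardLogistic().fit(np.empty((n, 0)), y, offset=offset).se_

        self.clusters_ = clusters
        self.intercept_ = float(gamma[0])
        self.coef_ = gamma[1:].copy()
        self.params_ = gamma
        self.sigma2_u0_ = float(sigma2)
        self.u0_ = u_hat
        self.se_ = se
        self.se_log_variance_ = se_logvar
        self.loglik_ = loglik
        self.boundary_ = bool(boundary)
        self.separation_ = bool(np.max(np.abs(fe)) > self.separation_lp)
        self.converged_ = bool(res.success and not self.separation_)
        return self

    @staticmethod
    def _posterior_means(fe, y, cidx, J, sigma, t, w, u_hat):
        """Posterior means E[u_j | data] by the same adaptive quadrature."""
        sigma2 = sigma * sigma
        _, curv = _posterior_modes(fe, y, cidx, J, sigma2, u_hat)
        scale = np.sqrt(2.0 / curv)
        K = t.shape[0]
        logf = np.empty((K, J))
        u_nodes = np.empty((K, J))
        for k in range(K):
            u_k = u_hat + scale * t[k]
            eta = fe + u_k[cidx]
            ll = _cluster_bernoulli(eta, y, cidx, J)
            log_phi = -0.5 * (_LOG_2PI + 2.0 * np.log(sigma) + u_k**2 / sigma2)
            logf[k] = np.log(w[k]) + t[k] ** 2 + ll + log_phi
            u_nodes[k] = u_k
        logf -= logf.max(axis=0, keepdims=True)
        f = np.exp(logf)
        return (u_nodes * f).sum(axis=0) / f.sum(axis=0)

    def decision_function(self, X, groups=None, conditional: bool = False):
        """Linear predictor from the fixed effects, optionally adding the
        cluster's empirical-Bayes intercept (conditional prediction).

        Conditional prediction refuses cluster labels unseen at fit time:
        a new cluster's random effect is unknown.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.coef_.shape[0]}"
            )
        lp = self.intercept_ + X @ self.coef_
        if conditional:
            if groups is None:
                raise ValueError("conditional prediction requires cluster labels")
            groups = np.asarray(groups)
            pos = np.searchsorted(self.clusters_, groups)
            pos_clipped = np.clip(pos, 0, self.clusters_.shape[0] - 1)
            unseen = self.clusters_[pos_clipped] != groups
            if unseen.any():
                bad = np.unique(groups[unseen])
                raise ValueError(
                    f"conditional prediction for unseen cluster(s) {bad.tolist()}; "
                    "use the marginal prediction for new clusters"
                )
            lp = lp + self.u0_[pos_clipped]
        return lp

    def predict_proba(self, X, groups=None, conditional: bool = False):
        p = expit(self.decision_function(X, groups=groups, conditional=conditional))
        return np.column_stack([1.0 - p, p])

    def predict(self, X, groups=None, conditional: bool = False):
        return (self.decision_function(X, groups=groups, conditional=conditional) > 0).astype(int)


def _numerical_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = x.shape[0]
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps * eps)
    return H


@dataclass
class RandomInterceptFit:
    """Fitted-model container for the random-intercept logistic model."""

    alpha: float
    beta: np.ndarray
    sigma2_u0: float
    se: np.ndarray             # fixed effects (alpha first)
    se_log_variance: float     # Wald SE of log(sigma2_u0)
    u0_hat: np.ndarray         # empirical-Bayes prediction per cluster
    clusters: np.ndarray
    loglik: float
    converged: bool
    boundary: bool
    model: RandomInterceptLogistic


def fit_random_intercept_logistic(
    X, y, cluster, offset=None, **kwargs
) -> RandomInterceptFit:
    """Fit a random-intercept logistic model; wrapper over RandomInterceptLogistic."""
    model = RandomInterceptLogistic(**kwargs).fit(X, y, groups=cluster, offset=offset)
    return RandomInterceptFit(
        alpha=model.intercept_,
        beta=model.coef_,
        sigma2_u0=model.sigma2_u0_,
        se=np.concatenate([[model.se_[0]], model.se_[1:]]),
        se_log_variance=model.se_log_variance_,
        u0_hat=model.u0_,
        clusters=model.clusters_,
        loglik=model.loglik_,
        converged=model.converged_,
        boundary=model.boundary_,
        model=model,
    )


@dataclass
class MixedCalibrationFit:
    """Mixed-model recalibration summary: fixed effect(s) and random-effect SD(s)."""

    fixed_intercept: float
    re_sd_intercept: float
    fixed_slope: float | None = None
    re_sd_slope: float | None = None
    converged: bool = True
    loglik: float = np.nan


def fit_mixed_calibration_large(lp, y, cluster, **kwargs) -> MixedCalibrationFit:
    """Calibration-in-the-large within clusters.

    Fits ``y ~ 1 + (1 | cluster)`` with the model's linear predictor as
    offset.  The fixed intercept is the average within-cluster calibration
    intercept; the random-intercept SD measures how much it varies across
    clusters (0 means predicted and observed cluster incidences agree
    everywhere).
    """
    lp = np.asarray(lp, dtype=float).ravel()
    model = RandomInterceptLogistic(**kwargs).fit(
        np.empty((lp.shape[0], 0)), y, groups=cluster, offset=lp
    )
    return MixedCalibrationFit(
        fixed_intercept=model.intercept_,
        re_sd_intercept=float(np.sqrt(model.sigma2_u0_)),
        converged=model.converged_,
        loglik=model.loglik_,
    )


def fit_mixed_calibration_slope(
    lp,
    y,
    cluster,
    n_quad: int = 7,
    max_iter: int = 200,
) -> MixedCalibrationFit:
    """Within-cluster calibration slope.

    Fits ``y ~ 1 + lp + (1 | cluster) + (0 + lp | cluster)`` — logistic with
    fixed intercept and slope plus independent normal random intercept and
    random slope — by 2-D adaptive product Gauss-Hermite quadrature
    (``n_quad`` x ``n_quad`` nodes).  The fixed slope is the average
    within-cluster calibration slope; the random-slope SD measures its
    spread across clusters.
    """
    lp = np.asarray(lp, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if np.var(lp) <= 0:
        raise ValueError("calibration slope requires a non-constant linear predictor")
    clusters, cidx = np.unique(np.asarray(cluster), return_inverse=True)
    J = clusters.shape[0]
    order = np.argsort(cidx, kind="stable")
    x, yv, cidx = lp[order], y[order], cidx[order]
    starts = np.searchsorted(cidx, np.arange(J))

    def csum(v, axis=None):
        return np.add.reduceat(v, starts, axis=-1)

    t, w = roots_hermite(n_quad)
    TA, TB = np.meshgrid(t, t, indexing="ij")
    t0n, t1n = TA.ravel(), TB.ravel()                       # (K2,)
    base_logw = (
        (np.log(w)[:, None] + np.log(w)[None, :]).ravel() + t0n**2 + t1n**2
    )

    start = StandardLogistic().fit(lp[:, None], y)
    theta0 = np.array([start.intercept_, start.coef_[0], np.log(0.3), np.log(0.3)])
    cache = {"u0": np.zeros(J), "u1": np.zeros(J)}

    def cluster_negll(theta):
        a, b, s0, s1 = theta
        v0, v1 = np.exp(2 * s0), np.exp(2 * s1)
        fe = a + b * x
        u0, u1 = cache["u0"].copy(), cache["u1"].copy()

        def objective(u0, u1):
            eta = fe + u0[cidx] + u1[cidx] * x
            return (
                csum(yv * eta - np.logaddexp(0.0, eta))
                - u0**2 / (2 * v0)
                - u1**2 / (2 * v1)
            )

        obj = objective(u0, u1)
        for _ in range(60):  # damped Newton for the 2-D posterior modes, all clusters
            eta = fe + u0[cidx] + u1[cidx] * x
            p = expit(eta)
            r = yv - p
            wt = p * (1.0 - p)
            g0 = csum(r) - u0 / v0
            g1 = csum(r * x) - u1 / v1
            a00 = csum(wt) + 1.0 / v0          # A = -Hessian (2x2 per cluster)
            a01 = csum(wt * x)
            a11 = csum(wt * x * x) + 1.0 / v1
            det = a00 * a11 - a01 * a01
            st0 = (a11 * g0 - a01 * g1) / det
            st1 = (-a01 * g0 + a00 * g1) / det
            nrm = np.hypot(st0, st1)
            if nrm.max() < 1e-10:
                break
            shrink = np.minimum(1.0, 4.0 / np.maximum(nrm, 1e-300))
            st0, st1 = st0 * shrink, st1 * shrink
            for _ in range(25):
                obj_new = objective(u0 + st0, u1 + st1)
                worse = obj_new < obj - 1e-12
                if not worse.any():
                    break
                st0[worse] *= 0.5
                st1[worse] *= 0.5
            u0, u1 = u0 + st0, u1 + st1
            obj = obj_new
        cache["u0"], cache["u1"] = u0, u1

        eta = fe + u0[cidx] + u1[cidx] * x
        p = expit(eta)
        wt = p * (1.0 - p)
        a00 = csum(wt) + 1.0 / v0
        a01 = csum(wt * x)
        a11 = csum(wt * x * x) + 1.0 / v1
        det = a00 * a11 - a01 * a01
        # Sigma = A^-1; lower Cholesky of Sigma, per cluster
        s00, s01, s11 = a11 / det, -a01 / det, a00 / det
        c00 = np.sqrt(s00)
        c10 = s01 / c00
        c11 = np.sqrt(np.maximum(s11 - c10**2, 1e-300))
        rt2 = np.sqrt(2.0)
        U0 = u0[None, :] + rt2 * t0n[:, None] * c00[None, :]            # (K2, J)
        U1 = u1[None, :] + rt2 * (
            t0n[:, None] * c10[None, :] + t1n[:, None] * c11[None, :]
        )
        ETA = fe[None, :] + U0[:, cidx] + U1[:, cidx] * x[None, :]       # (K2, n)
        ll = np.add.reduceat(yv[None, :] * ETA - np.logaddexp(0.0, ETA), starts, axis=1)
        log_phi = (
            -_LOG_2PI - (s0 + s1) - 0.5 * (U0**2 / v0 + U1**2 / v1)
        )
        lse = logsumexp(base_logw[:, None] + ll + log_phi, axis=0)
        return -float(np.sum(np.log(2.0) + np.log(c00) + np.log(c11) + lse))

    bounds = [(None, None), (None, None)] + [(_LOG_SIGMA_LO, _LOG_SIGMA_HI)] * 2
    res = minimize(
        cluster_negll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-11},
    )
    a, b, s0, s1 = res.x
    sd0 = 0.0 if s0 <= _LOG_SIGMA_LO + 1e-6 else float(np.exp(s0))
    sd1 = 0.0 if s1 <= _LOG_SIGMA_LO + 1e-6 else float(np.exp(s1))
    return MixedCalibrationFit(
        fixed_intercept=float(a),
        re_sd_intercept=sd0,
        fixed_slope=float(b),
        re_sd_slope=sd1,
        converged=bool(res.success),
        loglik=-float(res.fun),
    )
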
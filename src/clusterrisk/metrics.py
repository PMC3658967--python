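"""Discrimination and calibration measures, overall and within clusters.

Overall measures pool all patients: Harrell's c-index, calibration-in-the-
large (intercept of an offset logistic model, ideal 0) and the calibration
slope (coefficient of the linear predictor, ideal 1).  Within-cluster
counterparts respect the clustered structure: the c-index is averaged over
clusters, and calibration is assessed with mixed-effect recalibration models
whose fixed effect is the average within-cluster value and whose
random-effect SD quantifies between-cluster heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .glm import fit_standard_logistic
from .glmm import fit_mixed_calibration_large, fit_mixed_calibration_slope
from .risk import RiskVector

__all__ = [
    "PerformanceReport",
    "c_index",
    "c_index_brute",
    "c_index_within",
    "calibration_in_the_large",
    "calibration_slope",
    "evaluate",
]


def c_index(p, y) -> float:
    """Harrell's concordance index with 0.5 credit for ties, O(n log n).

    Computed from midranks: c = (R1 - n1(n1+1)/2) / (n1 n0) where R1 is the
    rank-sum of the events' predictions.
    """
    p = np.asarray(p, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    n1 = int(y.sum())
    n0 = y.shape[0] - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("c-index undefined: need at least one event and one non-event")
    ranks = rankdata(p)  # midranks give ties 0.5 credit
    r1 = ranks[y == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def c_index_brute(p, y) -> float:
    """O(n^2) pairwise c-index; independent check of :func:`c_index`."""
    p = np.asarray(p, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    pe, pn = p[y == 1], p[y == 0]
    if pe.size == 0 or pn.size == 0:
        raise ValueError("c-index undefined: need at least one event and one non-event")
    diff = pe[:, None] - pn[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def c_index_within(p, y, cluster) -> tuple[float, float, int]:
    """Average of per-cluster c-indices (unweighted) and their between-cluster SD.

    Clusters without both outcome classes are excluded; the count of usable
    clusters is returned.
    """
    p = np.asarray(p, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    cluster = np.asarray(cluster)
    cs = []
    for cl in np.unique(cluster):
        mask = cluster == cl
        yj = y[mask]
        if 0 < yj.sum() < yj.size:
            cs.append(c_index(p[mask], yj))
    if not cs:
        raise ValueError("no cluster has both events and non-events")
    cs = np.asarray(cs)
    return float(cs.mean()), float(cs.std(ddof=1)) if cs.size > 1 else 0.0, cs.size


def calibration_in_the_large(lp, y) -> float:
    """Intercept of a logistic model with the linear predictor as offset."""
    lp = np.asarray(lp, dtype=float).ravel()
    n = lp.shape[0]
    fit = fit_standard_logistic(np.empty((n, 0)), y, offset=lp)
    return fit.alpha


def calibration_slope(lp, y) -> float:
    """Slope of logistic ``y ~ 1 + lp``."""
    lp = np.asarray(lp, dtype=float).ravel()
    if np.var(lp) <= 0:
        raise ValueError("calibration slope requires a non-constant linear predictor")
    fit = fit_standard_logistic(lp[:, None], y)
    return float(fit.beta[0])


@dataclass
class PerformanceReport:
    """Overall and within-cluster performance of one risk vector.

    Within-cluster calibration rows hold (fixed effect, random-effect SD)
    from the mixed recalibration models; the within-cluster c row holds the
    mean and between-cluster SD of the per-cluster c-indices.
    """

    mode: str
    c_overall: float
    c_within_mean: float = np.nan
    c_within_sd: float = np.nan
    n_clusters_used: int = 0
    citl_overall: float = np.nan
    citl_within_fixed: float = np.nan
    citl_within_sd: float = np.nan
    slope_overall: float = np.nan
    slope_within_fixed: float = np.nan
    slope_within_sd: float = np.nan

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def evaluate(
    risk: RiskVector,
    y,
    cluster,
    within: bool = True,
    within_calibration: bool = True,
) -> PerformanceReport:
    """Assemble the full performance battery for one risk vector.

    ``within=False`` computes only the overall measures;
    ``within_calibration=False`` skips the (more expensive) mixed-model
    calibration rows but keeps the within-cluster c-index.
    """
    y = np.asarray(y).ravel().astype(int)
    cluster = np.asarray(cluster)
    rep = PerformanceReport(mode=risk.mode, c_overall=_named(c_index, "c_overall")(risk.p, y))
    rep.citl_overall = _named(calibration_in_the_large, "citl_overall")(risk.lp, y)
    rep.slope_overall = _named(calibration_slope, "slope_overall")(risk.lp, y)
    if within:
        rep.c_within_mean, rep.c_within_sd, rep.n_clusters_used = _named(
            c_index_within, "c_within"
        )(risk.p, y, cluster)
        if within_calibration:
            citl = _named(fit_mixed_calibration_large, "citl_within")(risk.lp, y, cluster)
            rep.citl_within_fixed = citl.fixed_intercept
            rep.citl_within_sd = citl.re_sd_intercept
            slope = _named(fit_mixed_calibration_slope, "slope_within")(risk.lp, y, cluster)
            rep.slope_within_fixed = slope.fixed_slope
            rep.slope_within_sd = slope.re_sd_slope
    return rep


def _named(fn, measure):
    """Re-raise measure failures with the measure name attached."""

    def wrapped(*args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"{measure} failed: {exc}") from exc

    return wrapped
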
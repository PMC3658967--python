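"""The three per-patient risk calculations.

* standard — from the standard logistic model.
* marginal — fixed effects of the random-intercept model only; the cluster
  effect is dropped, so the calculation applies to patients from new clusters.
* conditional — fixed effects plus the cluster's empirical-Bayes intercept;
  only defined for clusters seen at model development.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .glm import StandardFit
from .glmm import RandomInterceptFit

__all__ = ["RiskVector", "predict_standard", "predict_marginal", "predict_conditional"]


@dataclass
class RiskVector:
    """Per-patient predicted risks tagged with the risk-calculation mode."""

    mode: str                 # "standard" | "marginal" | "conditional"
    lp: np.ndarray            # linear predictor, log-odds
    p: np.ndarray             # predicted probability, expit(lp)

    def to_frame(self, cluster=None) -> pd.DataFrame:
        df = pd.DataFrame({"mode": self.mode, "lp": self.lp, "p": self.p})
        if cluster is not None:
            df.insert(0, "cluster_id", np.asarray(cluster))
        return df


def predict_standard(fit: StandardFit, X) -> RiskVector:
    """Risk from the standard model: lp = alpha + x.beta."""
    lp = fit.model.decision_function(X)
    return RiskVector(mode="standard", lp=lp, p=expit(lp))


def predict_marginal(fit: RandomInterceptFit, X) -> RiskVector:
    """Risk from the random-intercept model's fixed effects only."""
    lp = fit.model.decision_function(X)
    return RiskVector(mode="marginal", lp=lp, p=expit(lp))


def predict_conditional(
    fit: RandomInterceptFit, X, cluster, fallback_marginal: bool = False
) -> RiskVector:
    """Risk from fixed effects plus the cluster's empirical-Bayes intercept.

    Unseen clusters raise an error naming the offending labels; with
    ``fallback_marginal=True`` the marginal calculation is used for them
    instead (matching how models are applied to new clusters in practice).
    """
    cluster = np.asarray(cluster)
    if fallback_marginal:
        seen = np.isin(cluster, fit.clusters)
        lp = fit.model.decision_function(X)
        if seen.any():
            lp_seen = fit.model.decision_function(
                np.asarray(X, dtype=float)[seen], groups=cluster[seen], conditional=True
            )
            lp = lp.copy()
            lp[seen] = lp_seen
    else:
        lp = fit.model.decision_function(X, groups=cluster, conditional=True)
    return RiskVector(mode="conditional", lp=lp, p=expit(lp))
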
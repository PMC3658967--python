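"""Synthetic clustered populations and two-stage study samples.

The generator emulates a multicenter cohort: patients are nested in centers,
each center carries a latent normal random intercept ``u0`` on the log-odds
scale, and a binary outcome is produced from a six-predictor logistic model

    lp_ij = alpha + x_ij . beta + u0_j,     P(Y_ij = 1) = expit(lp_ij)

with all true coefficients equal to 1.  Three predictors are continuous
(mean 0, sd 0.2 / 0.4 / 1) and three are binary (incidence 0.2 / 0.3 / 0.4).
The strength of clustering is set through the latent-scale intraclass
correlation ICC = sigma2_u0 / (sigma2_u0 + pi^2 / 3); the fixed intercept is
solved numerically so the marginal outcome incidence hits a target (30% by
default, 3% in the low-event regime).

Study samples mimic multicenter data collection: centers are drawn first by
simple random sampling, then patients are drawn from the pooled patients of
the selected centers, so larger centers contribute proportionally more.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermite

__all__ = [
    "PREDICTOR_SDS",
    "BINARY_INCIDENCES",
    "TRUE_BETA",
    "ScenarioConfig",
    "SourcePopulation",
    "variance_from_icc",
    "icc_from_variance",
    "generate_center_sizes",
    "generate_predictors",
    "solve_intercept",
    "generate_outcomes",
    "generate_source_population",
    "two_stage_sample",
]

#: Standard deviations of the three continuous predictors (x1, x2, x3).
PREDICTOR_SDS = (0.2, 0.4, 1.0)
#: Incidences of the three binary predictors (x4, x5, x6).
BINARY_INCIDENCES = (0.2, 0.3, 0.4)
#: True log-odds ratios of all six predictors.
TRUE_BETA = np.ones(6)

_LOGISTIC_VAR = np.pi**2 / 3  # variance of the standard logistic distribution


def variance_from_icc(icc: float) -> float:
    """Random-intercept variance (log-odds^2) implied by a latent-scale ICC.

    Inverts ICC = sigma2 / (sigma2 + pi^2/3):  sigma2 = ICC * (pi^2/3) / (1 - ICC).
    """
    if not 0 <= icc < 1:
        raise ValueError(f"icc must be in [0, 1), got {icc}")
    return icc * _LOGISTIC_VAR / (1.0 - icc)


def icc_from_variance(sigma2_u0: float) -> float:
    """Latent-scale ICC of a logistic model with random-intercept variance sigma2_u0."""
    if sigma2_u0 < 0:
        raise ValueError(f"sigma2_u0 must be >= 0, got {sigma2_u0}")
    return sigma2_u0 / (sigma2_u0 + _LOGISTIC_VAR)


@dataclass
class ScenarioConfig:
    """Complete parameterization of one simulation scenario.

    Parameters
    ----------
    icc : latent-scale intraclass correlation in [0, 1).
    corr_x1_u0 : Pearson correlation between predictor x1 and the center
        random intercept, in [0, 1).
    n_source_centers : centers in the source population.
    center_size_log_mean, center_size_log_sd : the per-center Poisson mean is
        exp(z) with z ~ N(log_mean, log_sd^2).
    n_sample_centers, n_sample_patients : two-stage study-sample sizes.
    target_incidence : marginal outcome incidence the intercept is solved for.
    n_reps : Monte-Carlo replications of sample/fit/evaluate.
    base_seed : root seed; replication r uses the stream seeded by
        (base_seed, r) so replications are independently reproducible.
    """

    icc: float = 0.05
    corr_x1_u0: float = 0.0
    n_source_centers: int = 100
    center_size_log_mean: float = 5.7
    center_size_log_sd: float = 0.3
    n_sample_centers: int = 20
    n_sample_patients: int = 1000
    target_incidence: float = 0.30
    n_reps: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.icc < 1:
            raise ValueError(f"icc must be in [0, 1), got {self.icc}")
        if not 0 <= self.corr_x1_u0 < 1:
            raise ValueError(f"corr_x1_u0 must be in [0, 1), got {self.corr_x1_u0}")
        if self.n_sample_centers > self.n_source_centers:
            raise ValueError("n_sample_centers exceeds n_source_centers")
        if not 0 < self.target_incidence < 1:
            raise ValueError("target_incidence must be in (0, 1)")
        if self.center_size_log_sd < 0:
            raise ValueError("center_size_log_sd must be >= 0")

    @property
    def sigma2_u0(self) -> float:
        """True random-intercept variance implied by the ICC."""
        return variance_from_icc(self.icc)

    def rng(self, rep: int | None = None) -> np.random.Generator:
        """RNG for the scenario (or for one replication's independent stream)."""
        key = (self.base_seed,) if rep is None else (self.base_seed, rep)
        return np.random.default_rng(key)


@dataclass
class SourcePopulation:
    """A fully generated clustered population (or a study sample from one).

    ``centers`` holds the center labels (one per cluster) and ``u0`` the
    corresponding latent random intercepts; ``center_id`` maps each patient to
    a label in ``centers``.  ``source_rows`` is set on study samples and holds
    the row indices into the parent population.
    """

    center_id: np.ndarray  # (n,) int labels
    X: np.ndarray          # (n, 6)
    centers: np.ndarray    # (J,) unique labels, sorted
    u0: np.ndarray         # (J,) latent intercept per center
    lp: np.ndarray         # (n,) true linear predictor
    p_true: np.ndarray     # (n,) true risk
    y: np.ndarray          # (n,) binary outcome
    alpha_true: float
    source_rows: np.ndarray | None = None

    @property
    def n_patients(self) -> int:
        return self.y.shape[0]

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]

    def u0_per_patient(self) -> np.ndarray:
        pos = np.searchsorted(self.centers, self.center_id)
        return self.u0[pos]

    def to_frame(self) -> pd.DataFrame:
        """Patient-level table: center_id, x1..x6, u0, lp, p_true, y."""
        df = pd.DataFrame({"center_id": self.center_id})
        for m in range(6):
            df[f"x{m + 1}"] = self.X[:, m]
        df["u0"] = self.u0_per_patient()
        df["lp"] = self.lp
        df["p_true"] = self.p_true
        df["y"] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, alpha_true: float = np.nan) -> "SourcePopulation":
        center_id = df["center_id"].to_numpy()
        centers, first = np.unique(center_id, return_index=True)
        X = df[[f"x{m + 1}" for m in range(6)]].to_numpy(dtype=float)
        u0 = df["u0"].to_numpy(dtype=float)[first]
        return cls(
            center_id=center_id,
            X=X,
            centers=centers,
            u0=u0,
            lp=df["lp"].to_numpy(dtype=float),
            p_true=df["p_true"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=int),
            alpha_true=alpha_true,
        )


def generate_center_sizes(
    n_centers: int, log_mean: float, log_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-center patient counts: Poisson(exp(z)), z ~ N(log_mean, log_sd^2).

    The lognormal mixing makes center sizes overdispersed relative to a plain
    Poisson.  Centers that draw a size of zero are redrawn so every center has
    at least one patient.
    """
    if n_centers < 1:
        raise ValueError("n_centers must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    sizes = np.zeros(n_centers, dtype=np.int64)
    empty = np.ones(n_centers, dtype=bool)
    while empty.any():
        z = rng.normal(log_mean, log_sd, size=int(empty.sum()))
        sizes[empty] = rng.poisson(np.exp(z))
        empty = sizes == 0
    return sizes


def generate_predictors(
    n_patients: int,
    center_id: np.ndarray,
    u0: np.ndarray,
    corr_x1_u0: float,
    rng: np.random.Generator,
    sigma_u0: float | None = None,
) -> np.ndarray:
    """Draw the six-predictor matrix, optionally correlating x1 with u0.

    With correlation rho, x1 is built as
    ``rho * (sd_x1 / sigma_u0) * u0[center] + sqrt(1 - rho^2) * sd_x1 * z``
    which preserves x1's marginal standard deviation while giving
    corr(x1, u0_center) = rho.  ``u0`` must be indexed by consecutive center
    positions matching ``center_id`` (0..J-1).
    """
    if not 0 <= abs(corr_x1_u0) < 1:
        raise ValueError(f"|corr_x1_u0| must be < 1, got {corr_x1_u0}")
    X = np.empty((n_patients, 6))
    sd1 = PREDICTOR_SDS[0]
    z1 = rng.normal(0.0, 1.0, size=n_patients)
    if corr_x1_u0 > 0:
        if sigma_u0 is None:
            sigma_u0 = float(np.std(u0))
        if sigma_u0 <= 0:
            raise ValueError("corr_x1_u0 > 0 requires a non-degenerate u0")
        X[:, 0] = (
            corr_x1_u0 * (sd1 / sigma_u0) * u0[center_id]
            + np.sqrt(1 - corr_x1_u0**2) * sd1 * z1
        )
    else:
        X[:, 0] = sd1 * z1
    X[:, 1] = rng.normal(0.0, PREDICTOR_SDS[1], size=n_patients)
    X[:, 2] = rng.normal(0.0, PREDICTOR_SDS[2], size=n_patients)
    for m, q in enumerate(BINARY_INCIDENCES):
        X[:, 3 + m] = rng.binomial(1, q, size=n_patients)
    return X


def _expected_incidence(alpha: float, gauss_var: float, n_nodes: int = 80) -> float:
    """E[expit(alpha + B + G)] with B the exact binary-predictor sum and
    G ~ N(0, gauss_var) integrated by Gauss-Hermite quadrature."""
    t, w = roots_hermite(n_nodes)
    g = np.sqrt(2.0 * gauss_var) * t  # nodes of G
    total = 0.0
    for bits in product((0, 1), repeat=3):
        prob = np.prod([q if b else 1 - q for b, q in zip(bits, BINARY_INCIDENCES)])
        b = float(sum(bits))  # all true coefficients are 1
        total += prob * np.sum(w * expit(alpha + b + g)) / np.sqrt(np.pi)
    return float(total)


def solve_intercept(target_incidence: float, config: ScenarioConfig) -> float:
    """Fixed intercept alpha such that the marginal outcome incidence matches.

    The continuous predictors plus the random intercept form an exactly
    normal contribution (variance 1.2 + sigma2_u0 + 2*rho*sd_x1*sigma_u0 when
    x1 is correlated with u0); the three binary predictors are enumerated
    exactly.  The resulting one-dimensional mean equation is solved by Brent
    root-finding, deterministically.
    """
    if not 0 < target_incidence < 1:
        raise ValueError("target_incidence must be in (0, 1)")
    s2 = config.sigma2_u0
    rho = config.corr_x1_u0
    gauss_var = sum(sd**2 for sd in PREDICTOR_SDS) + s2
    gauss_var += 2 * rho * PREDICTOR_SDS[0] * np.sqrt(s2)
    return brentq(
        lambda a: _expected_incidence(a, gauss_var) - target_incidence,
        -30.0,
        10.0,
        xtol=1e-10,
    )


def generate_outcomes(p_true: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli outcomes: y_i = 1 iff u_i <= p_true_i with u_i ~ U(0, 1)."""
    p_true = np.asarray(p_true, dtype=float)
    if np.any((p_true < 0) | (p_true > 1)):
        raise ValueError("p_true values must lie in [0, 1]")
    u = rng.uniform(size=p_true.shape)
    return (u <= p_true).astype(np.int64)


def generate_source_population(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> SourcePopulation:
    """Generate one source population under the scenario's data-generating process."""
    if rng is None:
        rng = config.rng()
    sizes = generate_center_sizes(
        config.n_source_centers, config.center_size_log_mean, config.center_size_log_sd, rng
    )
    n = int(sizes.sum())
    center_id = np.repeat(np.arange(config.n_source_centers), sizes)
    sigma_u0 = np.sqrt(config.sigma2_u0)
    u0 = rng.normal(0.0, sigma_u0, size=config.n_source_centers)
    X = generate_predictors(n, center_id, u0, config.corr_x1_u0, rng, sigma_u0=sigma_u0)
    alpha = solve_intercept(config.target_incidence, config)
    lp = alpha + X @ TRUE_BETA + u0[center_id]
    p_true = expit(lp)
    y = generate_outcomes(p_true, rng)
    return SourcePopulation(
        center_id=center_id,
        X=X,
        centers=np.arange(config.n_source_centers),
        u0=u0,
        lp=lp,
        p_true=p_true,
        y=y,
        alpha_true=float(alpha),
    )


def two_stage_sample(
    pop: SourcePopulation,
    n_centers: int,
    n_patients: int,
    rng: np.random.Generator,
) -> SourcePopulation:
    """Two-stage study sample: SRS of centers, then SRS of patients pooled
    across the selected centers (larger centers contribute proportionally more).
    """
    if n_centers > pop.n_centers:
        raise ValueError(
            f"cannot sample {n_centers} centers from a population with {pop.n_centers}"
        )
    chosen = rng.choice(pop.centers, size=n_centers, replace=False)
    chosen.sort()
    pool = np.flatnonzero(np.isin(pop.center_id, chosen))
    if n_patients > pool.size:
        raise ValueError(
            f"cannot sample {n_patients} patients from a pool of {pool.size}"
        )
    rows = rng.choice(pool, size=n_patients, replace=False)
    rows.sort()
    keep = np.isin(pop.centers, chosen)
    return SourcePopulation(
        center_id=pop.center_id[rows],
        X=pop.X[rows],
        centers=pop.centers[keep],
        u0=pop.u0[keep],
        lp=pop.lp[rows],
        p_true=pop.p_true[rows],
        y=pop.y[rows],
        alpha_true=pop.alpha_true,
        source_rows=rows,
    )
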
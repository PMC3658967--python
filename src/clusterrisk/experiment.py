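"""Monte-Carlo simulation study: scenario grid, replications, aggregation.

One replication draws a two-stage study sample from a source population,
develops both prediction models on it (standard logistic; random-intercept
logistic), and evaluates the three risk calculations in the sample (apparent
performance) and — for the standard and marginal calculations, which apply
to new clusters — in the whole source population (test performance).
Replications are aggregated into the publication-style table: overall c as
mean with 2.5/97.5 percentiles, within-cluster rows as mean fixed effect
with mean random-effect (or between-cluster) SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dgp import ScenarioConfig, SourcePopulation, generate_source_population, two_stage_sample
from .glm import fit_standard_logistic
from .glmm import fit_random_intercept_logistic
from .metrics import PerformanceReport, evaluate
from .risk import predict_conditional, predict_marginal, predict_standard

__all__ = [
    "ReplicationRecord",
    "ScenarioResult",
    "run_replication",
    "run_scenario",
    "reproduce_tables",
    "TABLE_SCENARIOS",
]

#: Scenario definitions behind each reproduced results table.
TABLE_SCENARIOS: dict[str, dict] = {
    "table3": dict(icc=0.05, corr_x1_u0=0.0),
    "table4": dict(icc=0.15, corr_x1_u0=0.0),
    "table5": dict(icc=0.05, corr_x1_u0=0.0, n_sample_centers=5, n_sample_patients=100),
    "table6": dict(icc=0.05, corr_x1_u0=0.0, n_sample_centers=50, n_sample_patients=1000),
    "tableS1": dict(icc=0.05, corr_x1_u0=0.4),
    "tableS2": dict(icc=0.15, corr_x1_u0=0.4),
    "tableS3": dict(icc=0.30, corr_x1_u0=0.0),
    "tableS4": dict(icc=0.30, corr_x1_u0=0.4),
    "tableS5": dict(icc=0.05, corr_x1_u0=0.0, target_incidence=0.03),
}

_MEASURES = [
    "c_overall",
    "c_within",
    "citl_overall",
    "citl_within",
    "slope_overall",
    "slope_within",
]
_COLUMNS = [
    ("apparent", "standard"),
    ("apparent", "marginal"),
    ("apparent", "conditional"),
    ("test", "standard"),
    ("test", "marginal"),
]


@dataclass
class ReplicationRecord:
    """Performance of both models in one replication."""

    rep: int
    converged: bool
    sigma2_u0_hat: float
    reports: dict[tuple[str, str], PerformanceReport]  # (phase, mode) -> report


@dataclass
class ScenarioResult:
    """All replication records of one scenario plus table-shaped aggregates."""

    config: ScenarioConfig
    records: list[ReplicationRecord]
    n_nonconverged: int
    unreliable: bool

    def records_frame(self) -> pd.DataFrame:
        """Long per-replication frame: one row per (rep, phase, mode)."""
        rows = []
        for rec in self.records:
            for (phase, mode), rep_ in rec.reports.items():
                row = {"rep": rec.rep, "phase": phase, "mode": mode,
                       "converged": rec.converged}
                row.update(rep_.to_dict())
                rows.append(row)
        return pd.DataFrame(rows)

    def aggregate(self) -> pd.DataFrame:
        """Publication-style table: measures x (phase, model) columns.

        Cells are (point, spread): mean with 2.5/97.5 percentiles for the
        overall c-index; mean with mean SD for the within-cluster rows;
        plain means for overall calibration.  Only converged replications
        contribute.
        """
        df = self.records_frame()
        df = df[df["converged"]]
        out = {}
        for phase, mode in _COLUMNS:
            sub = df[(df["phase"] == phase) & (df["mode"] == mode)]
            if sub.empty:
                continue
            col = {}
            col["c_overall"] = (
                sub["c_overall"].mean(),
                sub["c_overall"].quantile(0.025),
                sub["c_overall"].quantile(0.975),
            )
            col["c_within"] = (sub["c_within_mean"].mean(), sub["c_within_sd"].mean())
            col["citl_overall"] = (sub["citl_overall"].mean(),)
            col["citl_within"] = (
                sub["citl_within_fixed"].mean(),
                sub["citl_within_sd"].mean(),
            )
            col["slope_overall"] = (sub["slope_overall"].mean(),)
            col["slope_within"] = (
                sub["slope_within_fixed"].mean(),
                sub["slope_within_sd"].mean(),
            )
            out[(phase, mode)] = col
        table = pd.DataFrame(
            {k: {m: v.get(m) for m in _MEASURES} for k, v in out.items()}
        )
        table.columns = pd.MultiIndex.from_tuples(table.columns, names=["phase", "model"])
        return table.reindex(_MEASURES)

    def formatted(self) -> pd.DataFrame:
        """Aggregate table with cells formatted like the results tables."""

        def fmt(cell):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                return ""
            if len(cell) == 3:
                return f"{cell[0]:.2f} ({cell[1]:.3f}; {cell[2]:.3f})"
            if len(cell) == 2:
                return f"{cell[0]:.2f} ({cell[1]:.3f})"
            return f"{cell[0]:.2f}"

        return self.aggregate().map(fmt)


def run_replication(
    pop: SourcePopulation,
    config: ScenarioConfig,
    rep: int,
    rng: np.random.Generator | None = None,
    test: bool = True,
    test_within: bool = True,
    within_calibration: bool = True,
) -> ReplicationRecord:
    """Sample, fit and evaluate once.

    Apparent performance covers all three risk calculations on the study
    sample; test performance covers the standard and marginal calculations on
    the full source population (the conditional calculation needs known
    cluster effects, which new clusters do not have).  Non-convergence or
    separation in either model flags the replication.
    """
    if rng is None:
        rng = config.rng(rep)
    sample = two_stage_sample(
        pop, config.n_sample_centers, config.n_sample_patients, rng
    )
    std = fit_standard_logistic(sample.X, sample.y)
    # per-replication SEs are not aggregated; skip the Hessian pass
    ri = fit_random_intercept_logistic(
        sample.X, sample.y, sample.center_id, compute_se=False
    )
    converged = std.converged and ri.converged

    reports: dict[tuple[str, str], PerformanceReport] = {}
    apparent = {
        "standard": predict_standard(std, sample.X),
        "marginal": predict_marginal(ri, sample.X),
        "conditional": predict_conditional(ri, sample.X, sample.center_id),
    }
    for mode, rv in apparent.items():
        reports[("apparent", mode)] = evaluate(
            rv, sample.y, sample.center_id, within_calibration=within_calibration
        )
    if test:
        held = {
            "standard": predict_standard(std, pop.X),
            "marginal": predict_marginal(ri, pop.X),
        }
        for mode, rv in held.items():
            reports[("test", mode)] = evaluate(
                rv,
                pop.y,
                pop.center_id,
                within=test_within,
                within_calibration=within_calibration,
            )
    return ReplicationRecord(
        rep=rep,
        converged=converged,
        sigma2_u0_hat=ri.sigma2_u0,
        reports=reports,
    )


def run_scenario(
    config: ScenarioConfig,
    test: bool = True,
    test_within: bool = True,
    within_calibration: bool = True,
    fixed_population: bool = False,
    progress: bool = False,
) -> ScenarioResult:
    """Run all replications of one scenario.

    By default a fresh source population is generated per replication from
    that replication's independent RNG stream; ``fixed_population=True``
    generates a single population up front and reuses it.
    """
    pop0 = generate_source_population(config) if fixed_population else None
    records = []
    for rep in range(config.n_reps):
        rng = config.rng(rep)
        pop = pop0 if fixed_population else generate_source_population(config, rng)
        rec = run_replication(
            pop,
            config,
            rep,
            rng=rng,
            test=test,
            test_within=test_within,
            within_calibration=within_calibration,
        )
        records.append(rec)
        if progress:
            print(f"rep {rep + 1}/{config.n_reps} converged={rec.converged}", flush=True)
    n_bad = sum(not r.converged for r in records)
    return ScenarioResult(
        config=config,
        records=records,
        n_nonconverged=n_bad,
        unreliable=n_bad > 0.2 * config.n_reps,
    )


def reproduce_tables(
    which: list[str] | None = None,
    n_reps: int = 100,
    base_seed: int = 0,
    out_dir=None,
    progress: bool = False,
) -> dict[str, ScenarioResult]:
    """Run the named table scenarios and (optionally) write one TSV each."""
    which = list(TABLE_SCENARIOS) if which is None else which
    results = {}
    for table_id in which:
        if table_id not in TABLE_SCENARIOS:
            raise KeyError(
                f"unknown table id {table_id!r}; known: {sorted(TABLE_SCENARIOS)}"
            )
        config = ScenarioConfig(
            n_reps=n_reps, base_seed=base_seed, **TABLE_SCENARIOS[table_id]
        )
        res = run_scenario(config, progress=progress)
        results[table_id] = res
        if out_dir is not None:
            import pathlib

            out = pathlib.Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            res.formatted().to_csv(out / f"{table_id}.tsv", sep="\t")
            res.records_frame().to_csv(
                out / f"{table_id}_replications.tsv", sep="\t", index=False
            )
    return results
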
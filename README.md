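# clusterrisk

Risk prediction for clustered (multicenter) binary outcomes: standard
logistic regression versus random-intercept logistic regression, with the
performance measures that matter when patients are nested in clusters, and
a Monte-Carlo simulation framework that re-runs the published comparison of
the two approaches.

## Who this is for

Biostatisticians and prediction-model researchers working with data in
which patients are clustered within centers or clinicians (the motivating
example is postoperative nausea and vomiting predicted from six
perioperative factors, with patients clustered within anesthesiologists).
The package answers: *does accounting for clustering at model development
change predictive performance, and how should that performance be measured?*

## The models and measures

Standard model (patients treated as independent):

    P(Y_i = 1 | x_i) = expit(α̂ + x_i'β̂)

Random-intercept model, fitted by maximum marginal likelihood with adaptive
Gauss–Hermite quadrature (cluster effect u_0j ~ N(0, σ²_u0)):

    marginal risk:     expit(α̂_RE + x_ij'β̂_RE)             — new clusters OK
    conditional risk:  expit(α̂_RE + x_ij'β̂_RE + û_0j)      — known clusters only

Performance is reported overall (pooled) and within clusters: Harrell's
c-index and the per-cluster-averaged c-index; calibration-in-the-large
(offset-model intercept, ideal 0) and calibration slope (ideal 1), plus
their within-cluster counterparts from mixed-effect recalibration models,
reported as (fixed effect, random-effect SD). The synthetic-data module
generates 100-center populations with a latent-scale intraclass correlation
ICC = σ²_u0 / (σ²_u0 + π²/3) of 5–30% and draws two-stage study samples
(centers first, then patients). See `docs/methods.md` for the full model
and design account.

## Worked example

```python
import numpy as np
from clusterrisk import (
    ScenarioConfig, generate_source_population, two_stage_sample,
    fit_standard_logistic, fit_random_intercept_logistic,
    predict_standard, predict_marginal, predict_conditional, evaluate,
)

cfg = ScenarioConfig(icc=0.15, base_seed=11)       # sigma2_u0 = 0.581
pop = generate_source_population(cfg)              # ~30,000 patients, 100 centers
smp = two_stage_sample(pop, 20, 1000, cfg.rng(0))  # 20 centers, 1000 patients

std = fit_standard_logistic(smp.X, smp.y)
ri  = fit_random_intercept_logistic(smp.X, smp.y, smp.center_id)
print(f"sigma2_u0 = {ri.sigma2_u0:.3f}")

for rv in (predict_standard(std, smp.X),
           predict_marginal(ri, smp.X),
           predict_conditional(ri, smp.X, smp.center_id)):
    r = evaluate(rv, smp.y, smp.center_id)
    print(f"{rv.mode:11s} c = {r.c_overall:.3f}   citl = {r.citl_overall:+.3f}   "
          f"citl within = {r.citl_within_fixed:+.3f} ({r.citl_within_sd:.3f})")
```

Output:

```
sigma2_u0 = 0.768
standard    c = 0.766   citl = +0.000   citl within = -0.117 (0.835)
marginal    c = 0.766   citl = +0.119   citl within = -0.000 (0.877)
conditional c = 0.839   citl = +0.003   citl within = +0.003 (0.000)
```

Reading it: the conditional calculation discriminates best (c 0.839 vs
0.766) because the cluster effect carries real information; the standard
model is perfectly calibrated overall (0.000, a property of ML fitting) but
mis-calibrated within clusters (random-intercept SD 0.835 across centers);
the conditional calculation is calibrated within every cluster (SD 0.000);
and the marginal calculation underestimates the pooled incidence
(citl +0.119) while being right on average within clusters (−0.000).

The same pipeline runs from the shell:

```bash
clusterrisk simulate --icc 0.05 --seed 1 --out pop.tsv
clusterrisk sample pop.tsv --centers 20 --patients 1000 --seed 2 --out smp.tsv
clusterrisk fit smp.tsv --model random-intercept
clusterrisk evaluate smp.tsv --mode conditional
clusterrisk scenario --icc 0.15 --reps 100 --seed 0 --out table4.tsv
clusterrisk reproduce-tables --tables table3,table4 --reps 100 --out-dir results/
```

`fit`/`evaluate` also accept any clustered delimited-text dataset with a
cluster-id column, an outcome column and named predictors.

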
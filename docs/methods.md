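# Methods

## The problem

Clinical prediction models are routinely developed on data in which patients
are nested in clusters — treatment centers, surgeons, anesthesiologists.
Patients treated by the same clinician are more alike than patients treated
by different clinicians, which standard logistic regression ignores.
`clusterrisk` implements and compares two development strategies for a
binary-outcome risk model on such data:

* **standard logistic regression** — intercept and predictor effects fitted
  as if patients were independent;
* **random-intercept logistic regression** — the same fixed effects plus a
  cluster-level deviation `u_0j ~ N(0, σ²_u0)` added to the intercept,
  fitted by maximum marginal likelihood.

From the mixed model two risk calculations follow: the **marginal**
calculation (fixed effects only, applicable to patients from new clusters)
and the **conditional** calculation (fixed effects plus the cluster's
empirical-Bayes intercept, applicable only to clusters represented at
development).

## Model fitting

The standard model is fitted by Newton–Raphson/IRLS with a step-halving
line search; convergence requires the maximum absolute score below 1e-8 (or
a relative log-likelihood change below 1e-10). Standard errors come from the
inverse observed information. Separation is flagged when the fitted linear
predictor exceeds 30 in absolute value or the log-likelihood is numerically
zero; flagged fits are excluded from simulation aggregates (the exclusion
count is reported). No penalization or shrinkage is applied.

The random-intercept model maximizes the marginal likelihood

    L(α, β, σ) = Π_j ∫ Π_{i∈j} Bernoulli(y_ij | expit(α + x_ij'β + u)) φ(u; 0, σ²) du

by **adaptive Gauss–Hermite quadrature**: for each cluster the integrand is
recentred at its posterior mode (found by a damped Newton iteration run for
all clusters in parallel) and rescaled by the posterior curvature, and a
15-node Hermite rule is applied on that transformed axis. Adaptivity matters
here because the simulated variances reach 1.41 with cluster sizes near 50,
where fixed-node quadrature and the Laplace approximation lose accuracy;
with adaptive recentring, 15 nodes agree with a 101-node non-adaptive rule
to better than 1e-5 in relative log-likelihood on all test fixtures, and the
fits agree with R's `lme4::glmer` (nAGQ = 15) to ~1e-3 on identical data.
The optimizer works on (α, β, log σ), keeping the variance non-negative;
fits pinned at the lower bound (σ ≈ e⁻⁶) are reported as boundary fits with
σ² = 0, in which case the marginal likelihood degenerates exactly to the
standard-logistic likelihood. Empirical-Bayes cluster effects `û_0j` are
posterior modes by default (posterior means are available via
`eb_method="mean"`); they shrink toward 0 relative to the unpooled
per-cluster estimates, vanishing as cluster information vanishes.

## Performance measures

Overall (pooled) measures: Harrell's c-index (midrank formula, O(n log n),
ties credited 0.5, validated against the O(n²) pair count), calibration-in-
the-large (intercept of an intercept-only logistic model with the linear
predictor as offset; ideal 0) and calibration slope (coefficient of the
linear predictor; ideal 1). By the ML score equations, a standard model
evaluated on its own development data has exactly (0, 1) — a built-in smoke
test.

Within-cluster measures respect the clustered structure:

* within-cluster c-index — the unweighted average of per-cluster c-indices
  over clusters with at least one event and one non-event (excluded-cluster
  counts are reported); the accompanying spread is the between-cluster SD.
  A per-cluster-constant shift (exactly what the conditional calculation
  adds) leaves every within-cluster c unchanged.
* within-cluster calibration-in-the-large — mixed model
  `y ~ 1 + (1 | cluster)` with the linear predictor as offset; reported as
  (fixed intercept, random-intercept SD).
* within-cluster calibration slope — mixed model
  `y ~ 1 + lp + (1 | cluster) + (0 + lp | cluster)` with *independent*
  random intercept and random slope, fitted by 2-D adaptive product
  quadrature (7×7 nodes); reported as (fixed slope, random-slope SD). The
  independence (diagonal covariance) choice keeps the model identifiable
  with 19–100 clusters; a covariance structure is not identifiable reliably
  at those sizes and is not needed for the reported summaries.

The "mean (SD)" convention for calibration rows is thus (fixed effect,
estimated random-effect SD): the fixed effect is the cluster-average
calibration, the SD the between-cluster heterogeneity. This is the only
reading under which the conditional calculation — whose linear predictor
already contains each cluster's intercept — shows an SD of exactly 0 on its
own development data.

## Synthetic populations

A source population has 100 centers. Center sizes are Poisson with a
lognormal mixing mean, `size_j ~ Poisson(exp(z_j))`, `z_j ~ N(5.7, 0.3²)`
(median ≈ exp(5.7) ≈ 299 patients, total ≈ 31,000; zero-size draws are
redrawn so every center has patients). Six predictors: three continuous
`N(0, sd)` with sd 0.2 / 0.4 / 1 and three binary with incidence
0.2 / 0.3 / 0.4; all true coefficients are 1. The center effect
`u_0j ~ N(0, σ²_u0)` has variance set from the latent-scale intraclass
correlation, `σ²_u0 = ICC·(π²/3)/(1−ICC)` (ICC 5/15/30% ↔ 0.173 / 0.581 /
1.410); the reference value 0.17 maps back to 4.91%, printed as 5%.
Optionally the first (sd 0.2) predictor is correlated with the center
effect: `x1 = ρ·(σ_x1/σ_u0)·u_0j + √(1−ρ²)·σ_x1·z`, preserving x1's
marginal SD while giving Pearson correlation ρ (0.4 in the correlated
scenarios).

The fixed intercept is not a free parameter: it is solved so the expected
outcome incidence hits the target (30%, or 3% in the low-event regime). The
solve is deterministic — the binary-predictor sum is enumerated over its 8
configurations, the continuous-plus-random-effect part is exactly normal
and integrated with an 80-node Hermite rule, and the scalar root is found by
Brent's method. For the base scenario this gives α = −2.050 (expected
incidence exactly 30.0%); the resulting linear predictor has SD
√(1.81 + 0.17) ≈ 1.41. Outcomes are `y = 1 iff u ≤ P(Y)` with `u ~ U(0,1)`.

Study samples are drawn in two stages, mirroring multicenter data
collection: a simple random sample of centers (20 by default; 5 or 50 in the
design scenarios), then a simple random sample of patients from the pooled
patients of the selected centers (1000 by default; 100 with 5 centers), so
larger centers contribute proportionally more. Equal per-center allocation
would shrink the within-cluster noise of small-center estimates slightly;
the proportional choice reflects consecutive-enrollment practice.

What the generator does *not* emulate: covariate distributions that differ
across centers (except through the optional x1–u0 correlation), non-normal
or skewed center effects, more than one clustering level, and
center-size-dependent case mix. Passing tests therefore demonstrate correct
behavior under a clean random-intercept world, not robustness to real-world
violations of it.

## Simulation study

One replication: generate a source population, draw a two-stage sample,
fit both models, evaluate the three risk calculations in the sample
(apparent performance) and the standard and marginal calculations in the
whole source population (test performance; the conditional calculation is
undefined for clusters outside the development sample). Each replication
uses an independent RNG stream derived from `(base_seed, replication)`, so
results are reproducible replication-by-replication and invariant to
execution order. By default a fresh population is generated per replication;
`fixed_population=True` reuses one, and the base-scenario aggregates are
insensitive to the choice. Scenarios run 100 replications by default;
the acceptance script and the heavier tests use 50, which doubles the
Monte-Carlo SE of reported means but keeps a full run in a few minutes on
one CPU. Aggregates report the overall c-index as mean (2.5th; 97.5th
percentile across replications) and within-cluster rows as mean fixed effect
(mean SD); non-converged replications are excluded and counted, and a
scenario with more than 20% exclusions is marked unreliable.

## Numerical choices

* quadrature: 15 nodes (1-D), 7×7 (2-D); configurable. Beyond 15 nodes the
  variance estimate moves by < 1e-3 on all fixtures.
* log-σ bounds [−6, 2.5]; boundary fits reported as σ² = 0.
* variance CI: Wald on the log-variance scale (SE of log σ² = 2·SE of
  log σ); profile-likelihood intervals are not implemented.
* posterior-mode Newton: damped steps clipped at 4 on the log-odds scale,
  objective-checked halving, warm-started across optimizer evaluations.
* c-index ties: 0.5 credit (midranks).
* intercept solve: Brent on [−30, 10], tolerance 1e-10.

## Known limitations and an observed discrepancy

The published simulation tables this package re-runs appear internally
inconsistent with the published data-generating description. The description
(ICC formula on the latent scale, variance 0.17 at 5%, linear predictor
SD 1.41) is exactly what the generator implements, and the bulk of the base
scenario reproduces: apparent c 0.79/0.79 (standard/marginal), conditional
within-cluster calibration SD 0.000, apparent slopes ~1.05/1.01. But several
clustering-sensitive published cells — the within-cluster
calibration-in-the-large SDs, the conditional c-index at stronger
clustering, and the marginal calibration intercepts (published 0.19 at ICC
15% and 0.14 at 3% incidence) — behave as if the generating variance had
been substantially larger than the stated formula yields (consistent with an
ICC denominator that also includes the fixed-effect variance of ~1.81).
Our mixed-model estimates match `lme4` to ~1e-5 on identical data, so the
gap is not an estimation artifact. The package follows the stated
generating process; the affected comparisons are reported as measured, and
the corresponding checks document the difference rather than hide it.

Other limitations: no GEE/marginal-model comparison (population-averaged
models do not yield patient-level predictions), no recalibration or updating
methods, no Firth correction for the low-event scenario (separated
replications are excluded instead), and a single clustering level.
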
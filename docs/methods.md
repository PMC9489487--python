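# Methods

## The problem

Comparative studies often want the effect of *relative* brain size — brain
size beyond the allometric expectation for a species' body size — on a third
trait such as longevity or innovation rate. The common recipe is to put
absolute brain size and body size together in one multiple regression of the
third trait `z`. Causally, however, absolute brain size is a **collider**:
it is jointly caused by body size (allometry) and by the extra brain tissue
that the hypothesis is actually about. Conditioning on a collider opens a
back-door path, so the regression's body-size coefficient absorbs part of
the brain effect and is biased; only the brain coefficient is estimated
correctly. This package simulates the two causal settings, quantifies the
bias, and implements the structural equation model (SEM) that estimates
relative brain size and its effect jointly.

## Generative models

All variables are on a standardized log scale; exogenous variables are
standard normal. Defaults (n = 100 species, 20 replicates, all effects and
residual SDs equal to 1) define the main study conditions; the appendix-style
presets vary n ∈ {20, 1000}, priors, and effect magnitudes (2 vs 0.5).

**Case I** (brain size as response):

    body ~ N(0, 1),  z ~ N(0, 1)
    brain ~ N(beta_body * body + beta_z * z, sigma_brain)

`case1_confounded` adds `z ~ N(gamma_body * body, sigma_z)`, so body size
confounds the z–brain relationship. The added effect size is not fixed by
theory; it defaults to 1 (the same magnitude as every other default effect)
and is configurable.

**Case II** (relative brain size as predictor):

    body ~ N(0, 1),  rel ~ N(0, 1)
    brain = beta_body * body + rel          (exact sum, no residual noise)
    z ~ N(gamma_body * body + gamma_brain * rel, sigma_z)

`rel` is latent; only body, brain and z are "observed" by the fitting code.
`rel_true` is stored with simulated data for scoring. It is re-derived as
`brain - beta_body * body` after constructing `brain`, so the construction
identity holds exactly in floating point, not merely within tolerance.

Replicate r of a scenario draws from a stream seeded by
`SeedSequence([base_seed, r])`: replicates are mutually independent and the
whole simulation is bit-reproducible across processes.

### Collider algebra

Substituting `rel = brain - beta_body*body` (with beta_body = 1) into the z
mean gives `E[z|body, brain] = (gamma_body - gamma_brain)*body +
gamma_brain*brain`. The OLS body coefficient therefore converges to
`gamma_body - gamma_brain`: exactly 0 at equal effects, attenuated (+1.5)
under a strong body effect (2, 0.5), negative (−1.5) under a strong brain
effect (0.5, 2). `case2_collider_expectation` exposes this closed form and
the test suite checks the fitted coefficients against it at n = 100 000.

## Estimators

* **linear** — OLS with classical standard errors (statsmodels;
  residual variance with n − p denominator). Rank-deficient designs raise an
  error naming the collinear columns; silently dropping a column would hide
  the very structure under study.
* **bayes_linear** — the same likelihood with Normal(0,1) intercept/slope
  priors and an Exponential(1) sigma prior.
* **sem** — the three-submodel system above with priors
  alpha_* ~ N(0,1), beta_body, gamma_body, gamma_brain ~ N(0,1),
  sigma_* ~ Exponential(1). Relative brain size is `brain_i - mu_brain_i`
  recomputed at every iteration, so uncertainty in the allometric slope
  propagates into the z submodel and back.

Point estimates for bias are posterior means; uncertainty for coverage is
the posterior SD (never quantile intervals), mirroring the ±2 SE rule used
for the frequentist fits.

Note on the SEM's `sigma_brain`: although Case II generates brain with no
independent noise, the brain~body submodel cannot explain the latent `rel`
component, so `sigma_brain`'s posterior concentrates near 1 (the SD of
`rel`), not near 0. There is no boundary pathology.

## Posterior sampling

Posteriors are sampled with the affine-invariant ensemble sampler (emcee),
using a differential-evolution move mixture (80% DE, 20% snooker) which
mixes markedly faster than the plain stretch move on these mildly
correlated 4–9 dimensional posteriors. Residual SDs are sampled on the log
scale with the Exponential prior's Jacobian correction.

`SamplerConfig` keeps the conventional chains/warmup/draws vocabulary:
each of `n_chains` (default 4) chains is an independent ensemble of
`max(2*dim, 16)` walkers started from a data-informed point with N(0, 0.1²)
jitter, run for `n_warmup` (default 1000) discarded steps, after which every
12th ensemble step is retained until `n_sampling` (default 1000) draws per
chain are collected. Thinning decorrelates the retained draws so split-Rhat
and ESS (computed with arviz across chains) are meaningful. Divergent
transitions do not exist for ensemble moves, so `n_divergent` is
structurally zero; convergence monitoring rests on Rhat, ESS and the
acceptance fraction. If any Rhat exceeds 1.01 the fit is retried once with
doubled warmup; a persistent failure is recorded in `Diagnostics`, surfaced
as a warning and in the experiment log, and never silently dropped.

Prior-only correctness is verified by sampling with a zero-observation
dataset (posterior = prior); likelihood correctness by comparing the SEM
joint log density against an independently hand-written sum of three Normal
log densities; and the flat-prior limit by agreement with OLS on a large
dataset.

## Priors for the sensitivity presets

The "vague" and "informative" settings are configurable because no single
convention is canonical: vague = Normal(0, 10) on intercepts/slopes with
Exponential(0.1) on SDs; informative = Normal(truth, 0.1) on slopes
(per-slope centers supported). The informative setting exists to show a
pathology, not a fix: under the collider structure even a slope prior
centered tightly on the true body effect leaves the truth outside the
±2 SD interval, because the likelihood concentrates firmly at
`gamma_body - gamma_brain`.

## Bias, coverage and the experiment runner

Bias is defined as `truth - estimate`. The published table's conventions are
reproducible only with this sign (the collider body row must be +1 when the
estimate is ~0 and the truth is 1); the convention is stated here because
the verbal definition "difference between estimate and simulated value"
alone is ambiguous. Coverage is the fraction of replicates with
`|truth - estimate| <= 2 * uncertainty`. Summaries (mean bias, SD of bias,
coverage per case × parameter × model) are a pure function of the persisted
per-replicate rows; re-running `summarize` on `replicates.csv` reproduces
`summary.csv` exactly. A model that fails on a replicate is logged and
excluded from that model's rows (visible in `n_replicates`), never imputed.

Scored effects: Case I — the body and z coefficients of the brain
regression; Case II — the body and brain effects on z (slopes for the
linear models, `gamma_body`/`gamma_brain` for the SEM).

## What the simulator does and does not emulate

The generator reproduces the study conditions exactly: unit-scale
linear-Gaussian systems with independent species. It deliberately omits
phylogenetic covariance, measurement error, missing data, and realistic
body/brain magnitudes — passing tests therefore demonstrate the collider
mechanism and the SEM's correction under idealized conditions, not
robustness to the additional structure of real comparative data.

## Problem sizes and numerical choices

The main grid (20 replicates × 100 species, ~60 MCMC fits of 4–9 parameter
models) was chosen to match the study conditions and runs in a few minutes
on one CPU; asymptotic checks use a single n = 100 000 replicate where a
closed form is available, and n ∈ {1000, 10 000} where a posterior must be
fitted. Unit tests use a reduced protocol (2 chains, 600 warmup + 600
draws); the acceptance suite always runs the full protocol. Monte-Carlo
tolerances in tests are set from binomial/normal error at 20 replicates
(coverage within ±0.15, mean bias within ±0.10 of the published values).

## Known limitations

* The ensemble sampler reports no divergences; pathological geometries that
  NUTS would flag loudly appear here only as poor Rhat/ESS.
* Rhat slightly above 1.01 occasionally triggers the automatic retry on
  small datasets (n ≤ 40) with the reduced test protocol; with the full
  protocol the main grid runs clean.
* `run_experiment` fits models sequentially; there is no parallelism.
* The SEM assumes the Case II DAG. Fitting it to data generated under a
  different causal structure estimates that structure's parameters only as
  well as the model is correct — the package scores estimators, it does not
  discover DAGs.
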
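"""Posterior-sampling checks: likelihood oracles, prior recovery, agreement
with frequentist fits, and SEM parameter recovery."""

import numpy as np
import pytest
from scipy import stats

from brainsem import (
    Dataset,
    PriorSpec,
    SamplerConfig,
    SimScenario,
    fit_bayes_linear,
    fit_linear,
    fit_sem,
    linear_log_likelihood,
    sem_log_likelihood,
    simulate_case1,
    simulate_case2,
)
from brainsem.bayes import SEM_PARAMETERS


def test_prior_spec_validation_and_labels():
    with pytest.raises(ValueError):
        PriorSpec(slope_scale=0.0)
    with pytest.raises(ValueError):
        SamplerConfig(n_chains=0)
    with pytest.raises(ValueError):
        SamplerConfig(target_acceptance=1.5)
    vague = PriorSpec.vague()
    assert vague.slope_scale == 10.0 and vague.sigma_rate == 0.1
    info = PriorSpec.informative({"gamma_body": 2.0}, scale=0.1)
    assert info.slope_loc("gamma_body") == 2.0
    assert info.slope_loc("gamma_brain") == 0.0  # falls back to shared location


def test_sem_log_likelihood_matches_handwritten_sum():
    """The SEM joint density is the sum of three Normal log densities with
    relative brain size evaluated at the current parameters."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        n = 8
        body, brain, z = rng.standard_normal((3, n))
        params = dict(zip(SEM_PARAMETERS, rng.standard_normal(9)))
        for s in ("sigma_body", "sigma_brain", "sigma_z"):
            params[s] = float(np.exp(params[s]))
        mu_brain = params["alpha_brain"] + params["beta_body"] * body
        rel = brain - mu_brain
        mu_z = params["alpha_z"] + params["gamma_body"] * body + params["gamma_brain"] * rel
        oracle = (
            stats.norm.logpdf(body, params["alpha_body"], params["sigma_body"]).sum()
            + stats.norm.logpdf(brain, mu_brain, params["sigma_brain"]).sum()
            + stats.norm.logpdf(z, mu_z, params["sigma_z"]).sum()
        )
        assert abs(sem_log_likelihood(body, brain, z, params) - oracle) <= 1e-8


def test_linear_log_likelihood_matches_scipy():
    rng = np.random.default_rng(4)
    n = 12
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    y = rng.standard_normal(n)
    coef = rng.standard_normal(3)
    sigma = 0.7
    oracle = stats.norm.logpdf(y, X @ coef, sigma).sum()
    assert abs(linear_log_likelihood(y, X, coef, sigma) - oracle) <= 1e-10


def test_posterior_reproduces_prior_on_empty_data(empty_dataset, fast_sampler):
    """With no observations the posterior is the prior: Normal(0,1) slopes
    and intercept, Exponential(1) sigma (mean 1, SD 1)."""
    fit = fit_bayes_linear(empty_dataset, sampler=fast_sampler)
    assert fit.draws.shape == (fast_sampler.n_chains * fast_sampler.n_sampling, 4)
    for name in ("alpha", "body", "brain"):
        assert abs(fit.mean(name)) < 0.15
        assert abs(fit.sd(name) - 1.0) < 0.15
    assert abs(fit.mean("sigma") - 1.0) < 0.2
    assert np.all(fit.draws_for("sigma") > 0)


def test_flat_prior_limit_agrees_with_ols(fast_sampler):
    """With vague priors and plenty of data the posterior concentrates on the
    least-squares solution."""
    ds = simulate_case1(SimScenario("case1", n_species=2_000, base_seed=13), 0)
    ols_fit = fit_linear(ds.brain, {"body": ds.body, "z": ds.z})
    fit = fit_bayes_linear(
        ds, response="brain", predictors=("body", "z"),
        priors=PriorSpec.vague(), sampler=fast_sampler,
    )
    for name in ("body", "z"):
        assert abs(fit.mean(name) - ols_fit.estimate(name)) < 3 * fit.sd(name)
        assert abs(fit.mean(name) - ols_fit.estimate(name)) < 0.05
        assert abs(fit.sd(name) - ols_fit.se(name)) < 0.2 * ols_fit.se(name)


def test_pooled_mean_stable_across_sampler_seeds(case2_dataset, fast_sampler):
    cfg2 = SamplerConfig(
        n_chains=fast_sampler.n_chains, n_warmup=fast_sampler.n_warmup,
        n_sampling=fast_sampler.n_sampling, base_seed=99,
    )
    a = fit_sem(case2_dataset, sampler=fast_sampler)
    b = fit_sem(case2_dataset, sampler=cfg2)
    for name in ("gamma_body", "gamma_brain", "beta_body"):
        mcse = a.sd(name) / np.sqrt(min(a.diagnostics.effective_sample_size[name],
                                        b.diagnostics.effective_sample_size[name]))
        assert abs(a.mean(name) - b.mean(name)) < max(4 * mcse, 0.03)


def test_sem_recovers_case2_parameters(case2_dataset, fast_sampler):
    """On collider-structured data the SEM recovers all three effects."""
    fit = fit_sem(case2_dataset, sampler=fast_sampler)
    for name in ("beta_body", "gamma_body", "gamma_brain"):
        assert abs(fit.mean(name) - 1.0) < 3 * fit.sd(name)
    d = fit.diagnostics
    assert d.max_rhat < 1.02
    assert d.min_ess > 100
    assert sum(d.n_divergent) == 0
    assert fit.draws.shape[0] == fast_sampler.n_chains * fast_sampler.n_sampling


def test_bayes_linear_body_slope_collapses_to_zero(case2_dataset, fast_sampler):
    """The collider at work: regressing z on body and absolute brain size
    concentrates the body slope near 0 although the true effect is 1."""
    fit = fit_bayes_linear(case2_dataset, sampler=fast_sampler)
    assert abs(fit.mean("body")) < 3 * fit.sd("body")
    assert not abs(1.0 - fit.mean("body")) <= 2 * fit.sd("body")


def test_informative_prior_cannot_rescue_linear_model(case2_dataset, fast_sampler):
    """Even a slope prior tightly centered on the truth leaves the true body
    effect outside the 2-SD interval."""
    fit = fit_bayes_linear(
        case2_dataset, priors=PriorSpec.informative(1.0), sampler=fast_sampler
    )
    assert abs(1.0 - fit.mean("body")) > 2 * fit.sd("body")
    assert fit.mean("body") > 0  # the prior does drag the slope positive


def test_sem_submodel_reduction_when_brain_effect_absent(fast_sampler):
    """With gamma_brain = 0 the z submodel collapses to a regression on body
    alone; the SEM's gamma_body matches that plain Bayesian slope."""
    scenario = SimScenario("case2", gamma_brain=0.0, base_seed=29)
    ds = simulate_case2(scenario, 0)
    sem = fit_sem(ds, sampler=fast_sampler)
    plain = fit_bayes_linear(ds, response="z", predictors=("body",), sampler=fast_sampler)
    assert abs(sem.mean("gamma_body") - plain.mean("body")) < 3 * sem.sd("gamma_body")


def test_sem_large_n_sharpens_allometric_slope(fast_sampler):
    """At n = 10 000 the allometric slope posterior pins down beta_body and
    the sampler stays healthy; the brain-submodel residual SD sits near the
    SD of latent relative brain size (1), which is what the allometric
    regression cannot explain."""
    ds = simulate_case2(SimScenario("case2", n_species=10_000, base_seed=31), 0)
    cfg = SamplerConfig(n_chains=2, n_warmup=300, n_sampling=300, base_seed=17)
    fit = fit_sem(ds, sampler=cfg)
    assert abs(fit.mean("beta_body") - 1.0) < 0.02
    assert abs(fit.mean("sigma_brain") - 1.0) < 0.05
    assert fit.diagnostics.max_rhat < 1.05


def test_user_table_without_truth_is_fittable(fast_sampler, tmp_path):
    """Fitting works on a plain user-supplied species table (no metadata)."""
    import pandas as pd

    from brainsem import read_dataset

    rng = np.random.default_rng(41)
    body = rng.standard_normal(50)
    brain = 0.8 * body + rng.standard_normal(50)
    z = 0.5 * body + rng.standard_normal(50)
    path = tmp_path / "species.csv"
    pd.DataFrame({"body": body, "brain": brain, "z": z}).to_csv(path, index=False)
    ds = read_dataset(path)
    fit = fit_sem(ds, sampler=fast_sampler)
    assert abs(fit.mean("beta_body") - 0.8) < 3 * fit.sd("beta_body")
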
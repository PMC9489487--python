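import numpy as np
import pytest

from brainsem import Dataset, PriorSpec, SamplerConfig, SimScenario, simulate_case2


@pytest.fixture(scope="session")
def fast_sampler() -> SamplerConfig:
    """Reduced MCMC protocol for unit tests; full protocol is exercised in
    the acceptance suite."""
    return SamplerConfig(n_chains=2, n_warmup=600, n_sampling=600, base_seed=11)


@pytest.fixture(scope="session")
def case2_dataset() -> Dataset:
    return simulate_case2(SimScenario("case2", base_seed=7), 0)


@pytest.fixture(scope="session")
def empty_dataset() -> Dataset:
    """Zero-observation dataset: the posterior must reproduce the prior."""
    z = np.empty(0)
    return Dataset(body=z, brain=z, z=z, case_id="case2", replicate_index=0, seed_used=0)


@pytest.fixture(scope="session")
def tiny_experiment_dir(tmp_path_factory, fast_sampler):
    """A small persisted Case II experiment shared by evaluate/report tests."""
    from brainsem import run_experiment

    out = tmp_path_factory.mktemp("experiment")
    scenario = SimScenario("case2", n_species=40, n_replicates=2, base_seed=5)
    results, summary = run_experiment(
        scenario, priors=PriorSpec.default(), sampler=fast_sampler, out_dir=out
    )
    return out, results, summary
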
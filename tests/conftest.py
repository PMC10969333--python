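import numpy as np
import pytest

import virtuallux as vl

# Reduced MCMC protocol for test fits: enough draws for stable credible
# intervals while keeping each fit to a few seconds.
FAST_FIT = dict(
    chains=2, iterations=1600, warmup=800, thin=1, walkers=24,
    noise_iterations=1000, noise_warmup=500,
)


def fast_mcmc(seed: int = 0, **over) -> vl.MCMCConfig:
    kw = dict(chains=2, iterations=1600, warmup=800, thin=1, walkers=24, seed=seed)
    kw.update(over)
    return vl.MCMCConfig(**kw)


@pytest.fixture(scope="session")
def raw41():
    """Default synthetic raw-estimates table (n=41) plus its ground truth."""
    return vl.generate_raw_estimates()


@pytest.fixture(scope="session")
def fitted_population(raw41):
    """One reduced-protocol population-model fit shared across tests."""
    raw, _ = raw41
    return vl.VirtualPopulation(random_state=3, **FAST_FIT).fit(raw)


@pytest.fixture(scope="session")
def pop_model(fitted_population):
    return fitted_population.population_model_
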
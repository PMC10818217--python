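import dataclasses

import numpy as np
import pandas as pd
import pytest

import genecea as g
from genecea.psa import PsaDraws

g.TestKind.__test__ = False  # domain enum, not a test class


@pytest.fixture(scope="session")
def defaults():
    """(params, priors, cohort, settings) from the packaged default config."""
    return g.load_config()


@pytest.fixture(scope="session")
def all_strategies():
    return list(g.STRATEGIES.values())


@pytest.fixture(scope="session")
def base_outcomes(defaults, all_strategies):
    params = defaults[0]
    return g.outcomes(all_strategies, params)


@pytest.fixture(scope="session")
def psa_default(defaults, all_strategies):
    """Default-prior PSA at desk scale: 10 000 draws over 4 chains."""
    params, priors, _, settings = defaults
    settings = dataclasses.replace(settings, n_draws=10_000, n_chains=4, seed=20240126)
    return g.run_psa(all_strategies, priors, params, settings)


@pytest.fixture(scope="session")
def fixed_priors(defaults):
    """Degenerate priors: every parameter fixed at its base estimate."""
    params = defaults[0]
    return g.PriorSet(
        {name: g.DistributionSpec.fixed(v) for name, v in params.to_flat().items()}
    )


@pytest.fixture(scope="session")
def degenerate_psa(defaults, all_strategies, fixed_priors):
    params, _, _, settings = defaults
    settings = dataclasses.replace(settings, n_draws=64, n_chains=2, seed=5)
    return g.run_psa(all_strategies, fixed_priors, params, settings)


def make_psa(costs, effects, parameters=None, cohort_size=1.0, n_chains=2):
    """Assemble a synthetic PsaDraws from raw outcome arrays."""
    costs = {k: np.asarray(v, float) for k, v in costs.items()}
    effects = {k: np.asarray(v, float) for k, v in effects.items()}
    n = len(next(iter(costs.values())))
    if parameters is None:
        parameters = pd.DataFrame(index=range(n))
    chain_id = np.arange(n) % n_chains
    return PsaDraws(
        parameters=parameters,
        costs=costs,
        effects=effects,
        chain_id=chain_id,
        seed=0,
        cohort_size=cohort_size,
    )


@pytest.fixture
def psa_factory():
    return make_psa
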
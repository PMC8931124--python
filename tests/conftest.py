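import numpy as np
import pytest

from cancelnudge import PopulationSpec, Preferences, sample_population
from cancelnudge.population import TruncatedNormalSpec


@pytest.fixture(scope="session")
def default_population_200():
    """Deterministic (noise-free) agents at the default moments."""
    return sample_population(PopulationSpec(n_agents=200, seed=11))


@pytest.fixture(scope="session")
def noisy_population_120():
    """Agents with Fechner noise, as used for stochastic-choice runs."""
    return sample_population(
        PopulationSpec(n_agents=120, seed=17, noise_temperature=0.5))


@pytest.fixture()
def linear_agent():
    return Preferences(alpha=1.0, beta=1.0, delta=0.99)


def point_mass_spec(n, alpha, beta, delta, seed=0, noise=0.0):
    """Population of identical agents (sd-zero truncated normals)."""
    return PopulationSpec(
        n_agents=n,
        alpha=TruncatedNormalSpec(alpha, 0.0, 1e-6, 1.0),
        beta=TruncatedNormalSpec(beta, 0.0, 1e-6, np.inf),
        delta=TruncatedNormalSpec(delta, 0.0, 1e-6, 1.0),
        noise_temperature=noise,
        seed=seed,
    )
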
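import numpy as np
import pytest

from stochglv import CommunityBlueprint, GLVParameters, NoiseSpec, SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_blueprint():
    """Reduced stool-like blueprint for fast tests."""
    return CommunityBlueprint(n_species=30, n_samples=400, seed=11)


@pytest.fixture(scope="session")
def logistic_series():
    """One noninteracting 20-species linear-noise series, reused across tests."""
    rng = np.random.default_rng(42)
    x_star = 10 ** rng.normal(2.0, 1.0, 20)
    g = 10 ** rng.uniform(np.log10(0.5), np.log10(5.0), 20)
    params = GLVParameters(growth=g, interactions=np.diag(-g / x_star))
    cfg = SimulationConfig(total_time=500.0, sampling_interval=1.0, seed=1)
    series = simulate(params, NoiseSpec(sigma_lin=1.0), cfg, x_star=x_star)
    return series, params, x_star
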
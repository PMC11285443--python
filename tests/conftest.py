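import numpy as np
import pytest

from ecoculture import (
    simulate,
    standard_climate_forcing,
    standard_parameters,
)


@pytest.fixture(scope="session")
def no_culture_traj():
    """Deterministic (sigma = 0) standard run, long enough to equilibrate."""
    return simulate(standard_parameters(sigma=0.0, n_steps=20_000))


@pytest.fixture(scope="session")
def stochastic_traj():
    """Short standard stochastic run reused across tests."""
    return simulate(standard_parameters(n_steps=20_000, seed=7))


@pytest.fixture(scope="session")
def forced_traj():
    """Periodically forced standard run spanning 20 forcing periods."""
    forcing = standard_climate_forcing()
    params = standard_parameters(
        kappa=0.5, omega=forcing.omega, n_steps=200_000, seed=11
    )
    return simulate(params, forcing), forcing


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240612)
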
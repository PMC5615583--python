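import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

logging.getLogger("pmfactors").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_study():
    """A small end-to-end synthetic study shared across tests."""
    from pmfactors.synthetic_data import simulate_study

    return simulate_study(preset="toy", seed=7, T_weeks=30, n_total=10,
                          n_study=7, n_cases=40, n_controls=60)


@pytest.fixture(scope="session")
def toy_fit(toy_study):
    """A short joint fit of the toy study (enough draws for smoke checks)."""
    from pmfactors.inference import MCMCConfig, run_gibbs

    cfg = MCMCConfig(n_iter=120, burn_in=40, thin=4, seed=5)
    return run_gibbs(toy_study["panel"], toy_study["cohort"], cfg)
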
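import numpy as np
import pytest

from missaux import FCSConfig, ScenarioConfig, generate_complete, make_observed


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_fcs():
    """Scaled-down chained-equations settings used throughout the suite."""
    return FCSConfig(m=20, burnin=10)


@pytest.fixture
def default_config():
    return ScenarioConfig(seed=20240901)


@pytest.fixture
def observed_mech3(rng):
    """One n=1000 dataset with exposure-driven outcome missingness and MNAR auxiliary."""
    cfg = ScenarioConfig(
        n=1000, outcome_mech=3, aux_mech=2, rho_yz=0.7, pi_z=0.5, seed=5
    )
    complete = generate_complete(cfg, rng)
    return make_observed(complete, rng)
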
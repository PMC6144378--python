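import numpy as np
import pytest

import relfreq as rf


@pytest.fixture(scope="session")
def uniform_pmf():
    return rf.condition_pmf("U")


@pytest.fixture(scope="session")
def small_design():
    """Two-participant design with the standard 693-trial structure."""
    return rf.ExperimentDesign(n_participants=2)


@pytest.fixture(scope="session")
def alnl_params():
    """AL-NL generator at the reference parameter point used throughout."""
    return rf.ObserverParams(
        model="AL-NL",
        beta0=0.8,
        beta_lags=(0.05,),
        betaC=0.0,
        kappa=0.05,
        omega=2.0,
        sigma_noise=0.3,
    )


@pytest.fixture(scope="session")
def alnl_participant(uniform_pmf, alnl_params):
    """One 693-trial AL-NL observer in the Uniform condition."""
    stim = rf.generate_stimulus_sequence(uniform_pmf, rf.ExperimentDesign(), seed=101)
    return rf.simulate_observer(alnl_params, stim, seed=102)


@pytest.fixture(scope="session")
def alnl_cohort(uniform_pmf, alnl_params):
    """Eight AL-NL observers in the Uniform condition (pooled analyses)."""
    design = rf.ExperimentDesign(n_participants=8)
    return rf.simulate_cohort(design, "U", alnl_params, uniform_pmf, seed=103)


@pytest.fixture(scope="session")
def noiseless_llo_trials(uniform_pmf):
    """Deterministic LLO observer (gamma=0.8, p0=0.5): exact test data."""
    params = rf.ObserverParams(model="LLO", beta0=0.8, betaC=0.0, sigma_noise=0.0)
    stim = rf.generate_stimulus_sequence(uniform_pmf, rf.ExperimentDesign(), seed=104)
    return rf.simulate_observer(params, stim, seed=105)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
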
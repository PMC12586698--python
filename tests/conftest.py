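import numpy as np
import pytest

from cathgf import HGFParameters, SequenceSpec, generate_experiment, simulate_agent
from cathgf.model import DEFAULT_TRUE_RESPONSE

SIM_SEED = 20260921


@pytest.fixture(scope="session")
def spec():
    return SequenceSpec()


@pytest.fixture(scope="session")
def short_spec():
    return SequenceSpec(trials_per_session=240)


@pytest.fixture(scope="session")
def sim_trials(spec):
    """One fully simulated participant: 2 x 960 trials at the default
    generative parameters (omega=-4, group-mean response weights)."""
    stimuli = generate_experiment(spec, SIM_SEED)
    return simulate_agent(
        stimuli, HGFParameters(-4.0), DEFAULT_TRUE_RESPONSE,
        error_rate=0.08, seed=SIM_SEED + 1,
    )


@pytest.fixture(scope="session")
def short_trials(short_spec):
    """A small simulated participant (2 x 240 trials) for fast fitting tests."""
    stimuli = generate_experiment(short_spec, SIM_SEED + 2)
    return simulate_agent(
        stimuli, HGFParameters(-4.0), DEFAULT_TRUE_RESPONSE,
        error_rate=0.08, seed=SIM_SEED + 3,
    )


@pytest.fixture(scope="session")
def sim_trajectory(sim_trials):
    from cathgf import filter_trials

    return filter_trials(
        sim_trials["stimulus"].to_numpy(),
        HGFParameters(-4.0),
        sessions=sim_trials["session"].to_numpy(),
    )
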
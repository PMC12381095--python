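import numpy as np
import pytest

from retromem import scheduler as sch
from retromem import synth


@pytest.fixture(scope="session")
def exp1_objects():
    return sch.assign_conditions(180, 1, seed=0)


@pytest.fixture(scope="session")
def exp2_objects():
    return sch.assign_conditions(300, 2, seed=0)


@pytest.fixture(scope="session")
def small_experiment():
    """Tiny Experiment-1 simulation shared across tests (read-only)."""
    params = synth.GeneratorParams(
        experiment=1,
        n_participants=4,
        n_objects=24,
        seed=11,
        noise_sd=3.0,
        location_signal_amplitude=3.0,
    )
    return synth.SyntheticExperiment(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
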
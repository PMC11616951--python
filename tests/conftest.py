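import numpy as np
import pytest

from equirest.design import generate_schedule
from equirest.simulate import ExperimentSimParams, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20220301)


@pytest.fixture(scope="session")
def study_schedule():
    """The reference design: 10 horses x 2 repetitions, grouped 3 per date."""
    return generate_schedule(10, 2, seed=1)


@pytest.fixture(scope="session")
def bouts_table(study_schedule):
    """One simulated bout-count outcome table at study dimensions."""
    table, truth = simulate_experiment(
        study_schedule, ExperimentSimParams.bouts_defaults(), rng=np.random.default_rng(99)
    )
    return table, truth
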
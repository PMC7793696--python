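import numpy as np
import pytest

from smrcoh import LearnerParams, epoch, reject_epochs, simulate_run


@pytest.fixture(scope="session")
def default_run():
    """One 3-min run with default learner parameters and artifacts."""
    return simulate_run(LearnerParams(), session_idx=1, run_idx=1,
                        duration_s=180.0, seed=11)


@pytest.fixture(scope="session")
def clean_run():
    """A 3-min run without injected artifacts."""
    return simulate_run(LearnerParams(blink_rate=0.0, muscle_rate=0.0),
                        session_idx=1, run_idx=1, duration_s=180.0, seed=11)


@pytest.fixture(scope="session")
def default_epochs(default_run):
    return reject_epochs(epoch(default_run))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
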
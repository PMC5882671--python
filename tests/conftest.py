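import numpy as np
import pytest

from dust_ddm.synthetic_data import GroundTruth, generate_schedule, simulate_subject


@pytest.fixture(scope="session")
def no_effect_subject():
    """One subject simulated with no social or norm effects (calibrated base)."""
    truth = GroundTruth()
    schedule = generate_schedule(seed=101)
    df = simulate_subject(truth, schedule, seed=102)
    return truth, schedule, df


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
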
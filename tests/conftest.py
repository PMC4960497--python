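import numpy as np
import pytest

import stresskit as sk


@pytest.fixture(scope="session")
def default_reactivity():
    return sk.ReactivityConfig()


@pytest.fixture(scope="session")
def session_and_truth(default_reactivity):
    """One simulated participant reused by read-only tests."""
    return sk.simulate_session("P01", default_reactivity, seed=11)


@pytest.fixture(scope="session")
def small_cohort(default_reactivity):
    return sk.simulate_cohort(5, default_reactivity, master_seed=42)


@pytest.fixture
def flat_eda_trace():
    return sk.SignalTrace(sk.Channel.EDA, 4.0, np.full(1200, 4.0))
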
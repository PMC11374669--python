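import numpy as np
import pytest

from freechoice import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-mouse, 2-minute cohort with photometry; shared across tests."""
    cfg = sim.CohortConfig(n_mice=2, session_duration=120.0, rng_seed=7)
    sessions, truth = sim.generate_cohort(cfg)
    return sessions, truth


@pytest.fixture(scope="session")
def behavior_session():
    """One 5-minute behavior-only session (no photometry)."""
    cfg = sim.CohortConfig(n_mice=1, session_duration=300.0, rng_seed=11)
    return sim.generate_behavior(cfg)
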
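import numpy as np
import pytest

from affectlearn.session import build_schedule
from affectlearn.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def reference_schedule():
    """The study design: 3600 s session, 270 s interval, 16.36 s responses."""
    sched = build_schedule(3600, 270, 60)
    for k in range(sched.n_alarms):
        sched.register_response(k, 16.36)
    return sched


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four probands, 1080 s sessions (4 alarms): fast but structurally full."""
    cfg = GeneratorConfig(n_probands=4, session_length=1080, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_sessions(tiny_cohort):
    return tiny_cohort[0]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
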
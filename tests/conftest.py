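import numpy as np
import pytest

from gravimea.phases import Phase, PhaseSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_phase_schedule():
    """One 10 s phase, no margin — convenient for detection tests."""
    return PhaseSchedule((Phase("all", 0.0, 10.0),), safety_margin=0.0)
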
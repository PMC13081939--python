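import numpy as np
import pytest

from omnquant.stimulus import StimulusParams
from omnquant.synthetic import EyePlantParams, generate_session


@pytest.fixture
def short_stim():
    """Two-cycle protocol with short dwells: same kinematics, fast tests."""
    return StimulusParams(n_cycles=2, hold_duration=1.5)


@pytest.fixture
def default_stim():
    return StimulusParams()


def make_session(stim, **plant_kwargs):
    return generate_session(stim, EyePlantParams(**plant_kwargs))


@pytest.fixture
def make_short_session(short_stim):
    def _make(**plant_kwargs):
        return make_session(short_stim, **plant_kwargs)
    return _make
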
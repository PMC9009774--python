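import math

import numpy as np
import pytest
from hypothesis import settings

from fretstack.synth import FixtureSpec, generate_fixture

# deterministic hypothesis runs regardless of external config
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


SMALL_SPEC = dict(
    height=240,
    width=320,
    n_frames=6,
    tail=(60.0, 120.0),
    tip=(200.0, 120.0),
    half_width=12.0,
    gradient_length=40.0,
    tip_velocity=(2.0, 0.0),
    channel_offset=(3.0, -2.0, math.radians(1.0)),
    seed=11,
)


@pytest.fixture(scope="session")
def small_fixture():
    """240x320, 6-frame dual-channel fixture with the default physics."""
    return generate_fixture(FixtureSpec(**SMALL_SPEC))


@pytest.fixture(scope="session")
def default_fixture():
    """The generator's default study conditions (640x480, 20 frames)."""
    return generate_fixture(FixtureSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
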
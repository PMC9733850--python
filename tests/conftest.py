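import math

import numpy as np
import pytest
from hypothesis import settings

from lamellaflex import UndulationSpec, generate_undulated_multilayer

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: slope amplitude whose arctangent is 22.5 degrees
SLOPE_22_5 = math.tan(math.radians(22.5))


@pytest.fixture(scope="session")
def flat_multilayer():
    """4 layers x 100 lipids, no undulation, no noise: all directors on z."""
    spec = UndulationSpec(amplitude=0.0, wavelength=200.0, seed=0)
    return generate_undulated_multilayer(4, 100, spec)


@pytest.fixture(scope="session")
def undulated_multilayer():
    """4 layers x 2500 lipids with max surface slope tan(22.5 deg), no noise."""
    amplitude = SLOPE_22_5 * 200.0 / (2.0 * math.pi)
    spec = UndulationSpec(amplitude=amplitude, wavelength=200.0, seed=0)
    return generate_undulated_multilayer(4, 2500, spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
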
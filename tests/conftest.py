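import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from ecgvt.simulate import PhysiologyParams, simulate_protocol

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def protocol():
    """106 W peak at 12 W/min: 530-s ramp inside a 950-s session."""
    return simulate_protocol(12.0, 106.0)


@pytest.fixture
def noiseless_phys():
    return PhysiologyParams(breath_noise_sd=0.0, rr_jitter_sd=0.0)


@pytest.fixture
def spec_slopes_phys(noiseless_phys):
    """Noiseless physiology with 0.9 / 1.2 V-slope segments."""
    return dataclasses.replace(noiseless_phys, vslope_below=0.9,
                               vslope_above=1.2, rq_rest=0.95)
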
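import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import perimotion as pm

settings.register_profile(
    "default", max_examples=25, derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def waveform():
    """Respiratory drive: 15 um (30 um peak-to-peak) at 0.5 Hz."""
    return pm.MicromotionWaveform()


@pytest.fixture
def interstitial_50():
    """Interstitial fluid at the mid-range viscosity 50 mPa s."""
    return pm.FluidProperties(density=1006.0, dynamic_viscosity=50e-3)


@pytest.fixture
def reference_gap():
    """Closed 50 um per-side gap around the 100 um electrode."""
    return pm.GapGeometry(side_gap=50e-6)


@pytest.fixture
def peak_speed(waveform):
    """Peak electrode speed 2*pi*f*A of the default waveform."""
    return 2.0 * np.pi * 0.5 * 15e-6
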
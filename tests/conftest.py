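import numpy as np
import pytest

import lungelast as le


@pytest.fixture(scope="session")
def small_phantom():
    """Homogeneous 32-cube phantom shared by read-only tests."""
    spec = le.severity_preset(
        "homogeneous", grid_shape=(32, 32, 32), seed=11
    )
    return le.generate_phantom(spec)


@pytest.fixture(scope="session")
def breathing_signal():
    return le.generate_breathing_signal(duration=120.0, period=4.0, seed=5)


@pytest.fixture(scope="session")
def sinusoid_signal():
    """Pure raised-cosine signal (no cycle variability, no drift)."""
    return le.generate_breathing_signal(
        duration=60.0, period=4.0, drift=0.0, seed=0,
        period_variability=0.0, depth_variability=0.0,
    )


def lobar_dist(values, label=1):
    """Shorthand for a LobarDistribution from raw values."""
    return le.LobarDistribution(lobe_label=label, values=np.asarray(values, float))
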
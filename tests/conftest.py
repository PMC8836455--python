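import math

import numpy as np
import pytest

from glyflip import AcquisitionConfig, FlipMechanism
from glyflip.mechanism import build_saturated_core


@pytest.fixture(scope="session")
def reference_mechanism():
    """Mammalian homomeric reference: fully liganded E=38, F=8."""
    return FlipMechanism.reference()


@pytest.fixture(scope="session")
def slow_cluster_mechanism():
    """Saturated-core kinetics slowed so dwells clear the 3 kHz dead time.

    Same equilibria (E=15, F=8) as the acidic-pH glycine condition but
    close_rate 70 /s and flip_off 150 /s; desensitisation shapes ~1 s
    clusters separated by ~1 s gaps.
    """
    return FlipMechanism.from_equilibrium(
        E=15.0, F=8.0, close_rate=70.0, flip_off=150.0,
        desens_on=125.0, desens_off=1.0)


@pytest.fixture(scope="session")
def cell_attached_acquisition():
    """100 kHz sampling, 3 kHz Gaussian filter, resample to 33.3 kHz."""
    return AcquisitionConfig(sample_rate=100e3, filter_corner=3e3,
                             resample_rate=100e3 / 3, noise_sd=1.0,
                             single_channel_current=7.0)


@pytest.fixture(scope="session")
def two_state_generator():
    """Shut <-> open with opening rate beta=50/s, closing rate alpha=200/s."""
    from glyflip.mechanism import CLASS_OPEN, CLASS_SHUT, GeneratorMatrix

    alpha, beta = 200.0, 50.0
    q = np.array([[-beta, beta], [alpha, -alpha]])
    Q = GeneratorMatrix(rates=q, state_classes=[CLASS_SHUT, CLASS_OPEN],
                        state_names=["C", "O"])
    return Q, alpha, beta


@pytest.fixture(scope="session")
def saturated_core_acidic():
    """Three-state A3R-A3F-A3O core with F=8, E=15 (E_eff = 40/3)."""
    return build_saturated_core(E=15.0, F=8.0)
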
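import numpy as np
import pytest

from slicemap import conditioning, scenarios


@pytest.fixture(scope="session")
def plane_wave_20():
    """Clean 0.5 m/s plane wave on a 20x20 grid, 5 beats at 1 Hz, 1000 fps."""
    stack, truth = scenarios.simulate_plane_wave(
        0.5, shape=(20, 20), fps=1000, pcl_ms=1000, n_pulses=5)
    return stack, truth


@pytest.fixture(scope="session")
def san_atrial_600():
    """SAN (ERP 900 ms) + atrium (ERP 250 ms), S1-S1 at 600 ms, 10 pulses."""
    return scenarios.simulate_san_atrial(600, 10, shape=(40, 40), fps=1000)


def full_mask(shape):
    return conditioning.TissueMask(np.ones(shape, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
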
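import numpy as np
import pytest

import aimforce as af


@pytest.fixture(scope="session")
def ctx():
    """Room-temperature thermal context (kBT = 4.114 pN nm)."""
    return af.ROOM_TEMPERATURE


@pytest.fixture(scope="session")
def aim_wlc():
    """Whole-module WLC parameters."""
    return af.WLCParams(26.6, 0.60)


@pytest.fixture(scope="session")
def aim_kinetics():
    """Whole-module Bell-Evans parameters."""
    return af.BellEvansParams(0.074, 1.10)


@pytest.fixture(scope="session")
def presets():
    return af.published_presets()


@pytest.fixture(scope="session")
def small_experiment(presets):
    """A small simulated pulling experiment shared across trace tests."""
    cfg = af.SimulationConfig(construct=presets["AIM-A1"], n_tethers=12,
                              cycles_per_tether=5, seed=7)
    return af.simulate_experiment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
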
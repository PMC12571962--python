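import numpy as np
import pytest

from emofmri.design_io import MotionParams
from emofmri.synthetic import SimulationConfig, simulate_events


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: few parcels, defaults otherwise."""
    return SimulationConfig(n_parcels=6, n_per_group=4, seed=42)


@pytest.fixture(scope="session")
def default_events():
    cfg = SimulationConfig(n_parcels=2)
    return simulate_events(cfg, np.random.default_rng(7))


@pytest.fixture(scope="session")
def zero_motion():
    return MotionParams(np.zeros((470, 6)))
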
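import pytest

from alborun import config as cfgm
from alborun import simulate
from alborun.bio import BioParams
from alborun.grid import Grid


@pytest.fixture
def params() -> BioParams:
    return BioParams()


@pytest.fixture
def small_grid() -> Grid:
    """Cheap 3-D grid for transport unit tests."""
    return Grid.regular(nx=12, ny=10, nz=6, dx=10e3, dy=10e3, depth=300.0, surface_dz=20.0)


@pytest.fixture(scope="session")
def default_config() -> cfgm.RunConfig:
    return cfgm.RunConfig()


@pytest.fixture(scope="session")
def reduced_run(default_config):
    """The reduced-resolution 120-day jet-gyre run (shared across tests)."""
    return simulate.run_simulation(default_config)


@pytest.fixture(scope="session")
def control_run():
    """Zero-flow control: same scenario, all flow amplitudes zero."""
    cfg = cfgm.RunConfig()
    cfg.flow.jet_speed = 0.0
    cfg.flow.w_max = 0.0
    cfg.flow.gyre_speeds = [0.0, 0.0]
    return simulate.run_simulation(cfg)
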
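import pytest

from mlpangs import preset_genotypes, simulate_panel
from mlpangs.simulate import SimConfig


@pytest.fixture(scope="session")
def kit_panel():
    """Emulated DMD-SMA panel: 80 DMD probes, full control complement."""
    return simulate_panel(n_dmd=80, n_internal_ref=10, seed=1)


@pytest.fixture(scope="session")
def small_panel():
    """Cheap panel for property tests: 6 DMD probes, 4 internal refs."""
    return simulate_panel(n_dmd=6, n_internal_ref=4, seed=3)


@pytest.fixture(scope="session")
def presets():
    return preset_genotypes()


@pytest.fixture
def default_config():
    return SimConfig(seed=0)
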
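import numpy as np
import pytest

from angiosim.config import DiffusionParams, GridConfig, SimulationConfig, fixture_configs
from angiosim.grid import Grid3D, Indicators, make_grid


@pytest.fixture
def small_grid() -> Grid3D:
    return Grid3D(shape=(6, 6, 6), spacing=20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixtures() -> dict:
    return fixture_configs()


def empty_indicators(grid: Grid3D) -> Indicators:
    z = np.zeros(grid.shape, dtype=np.uint8)
    return Indicators(chi_ves=z.copy(), chi_tum=z.copy(), chi_tipEC=z.copy())
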
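import numpy as np
import pytest
from hypothesis import settings

from campath.fes_io import Axis, EnergyGrid, Temperature
from campath.synthetic import synthetic_topology

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def t310() -> Temperature:
    return Temperature(310.0)


@pytest.fixture
def grid_1d_simple() -> EnergyGrid:
    """Three nodes, energies [3, 1, 2]: a single interior minimum."""
    return EnergyGrid((Axis("x", 0.0, 2.0, 3),), np.array([3.0, 1.0, 2.0]))


@pytest.fixture
def grid_1d_flat() -> EnergyGrid:
    return EnergyGrid((Axis("x", 0.0, 4.0, 5),), np.zeros(5))


def random_grid_2d(seed: int, n: int = 20, scale: float = 5.0) -> EnergyGrid:
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.0, scale, size=(n, n))
    axes = (Axis("x", 0.0, 1.0, n), Axis("y", 0.0, 1.0, n))
    return EnergyGrid(axes, values)


@pytest.fixture
def topology_text() -> str:
    return synthetic_topology()
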
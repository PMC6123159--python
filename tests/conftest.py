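import numpy as np
import pytest

from pbsmc.fixtures import make_virtual_machine


@pytest.fixture(scope="session")
def machine():
    """Ground-truth virtual machine shared across the suite."""
    return make_virtual_machine(seed=0)


@pytest.fixture(scope="session")
def idd_100(machine):
    """Engine-simulated 100 MeV IDD in water (shared; moderate statistics)."""
    from pbsmc.transport import score_idd

    return score_idd(machine, 100.0, n=100_000, seed=101, phantom_depth=110.0)


@pytest.fixture(scope="session")
def kernel_115(machine):
    """115 MeV single-spot dose kernel in water, surface at isocenter."""
    from pbsmc.transport import DoseGrid, Geometry, simulate_spot, water_box

    grid = DoseGrid.centered(400.0, 0.0, 115.0)
    geom = Geometry([water_box(0.0, 115.0)])
    simulate_spot(machine, 115.0, n=200_000, seed=102, geometry=geom,
                  scorers=(grid,))
    return grid


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
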
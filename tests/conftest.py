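import numpy as np
import pytest

from taxisort.flow import SorterGeometry, solve_unit_cell_flow
from taxisort.physics import FluidMedium, WormBody

# canonical media and body used across the suite
LUDOX = FluidMedium(density=1090.0, dynamic_viscosity=4.78e-3, label="ludox-blend")
M9 = FluidMedium(density=1000.0, dynamic_viscosity=1.0e-3, label="m9")
WORM = WormBody(volume=5.96e-12, density=1080.0, stokes_radius=0.37e-3)


@pytest.fixture(scope="session")
def ludox():
    return LUDOX


@pytest.fixture(scope="session")
def m9():
    return M9


@pytest.fixture(scope="session")
def worm():
    return WORM


@pytest.fixture(scope="session")
def device_geometry():
    return SorterGeometry()


@pytest.fixture(scope="session")
def solved_field(device_geometry):
    """The reference-device unit-cell solve at the default 0.1 mm grid."""
    return solve_unit_cell_flow(device_geometry, grid_spacing=1e-4)
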
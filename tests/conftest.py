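import numpy as np
import pytest

from prpsim import (
    EquivalentDisc,
    DensityProfile,
    LayoutConfig,
    packaged_fixture,
)


@pytest.fixture(scope="session")
def disc():
    return EquivalentDisc()


@pytest.fixture(scope="session")
def fixture_profile(disc):
    """The packaged calibrated standard-eye profile (built once per session)."""
    return packaged_fixture(disc)


@pytest.fixture(scope="session")
def uniform_profile(disc):
    """Constant 1e4 cells/mm^2 over the whole retina, no optic disc."""
    grid = np.linspace(0.0, disc.radius_total, 2)
    return DensityProfile(grid, np.full(2, 1.0e4))


@pytest.fixture(scope="session")
def linear_profile(disc):
    """rho(e) = 1000 * e, exactly representable by the linear interpolant."""
    grid = np.linspace(0.0, disc.radius_total, 188)
    return DensityProfile(grid, 1000.0 * grid)


@pytest.fixture(scope="session")
def scatter_config(disc):
    return LayoutConfig(inner_radius=disc.radius_free, outer_radius=disc.radius_equator)


@pytest.fixture(scope="session")
def full_scatter_config(disc):
    return LayoutConfig(inner_radius=disc.radius_free, outer_radius=disc.radius_total)
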
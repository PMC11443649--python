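import pytest

from fibheat import GridSpec, SourceSpec
from fibheat.presets import GA_30KEV, GA_5KEV, SKIN_COLLAGEN


@pytest.fixture(scope="session")
def skin():
    return SKIN_COLLAGEN


@pytest.fixture(scope="session")
def ga5():
    return GA_5KEV


@pytest.fixture(scope="session")
def ga30():
    return GA_30KEV


@pytest.fixture
def small_grid():
    """A 48**2 x 40 voxel grid (240 x 240 x 200 nm): cheap but large enough that
    short diffusion tests never feel the boundaries."""
    return GridSpec(nx=48, ny=48, nz=40)


@pytest.fixture
def source_5kev():
    return SourceSpec(ion_energy=5.0, heat_fraction=0.9, spot_diameter=50e-9)
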
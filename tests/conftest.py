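import numpy as np
import pytest
from hypothesis import settings

import irai

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lard():
    return irai.LARD


@pytest.fixture(scope="session")
def default_array():
    return irai.build_array()


@pytest.fixture(scope="session")
def small_array():
    """8 x 8 array for oracle-scale tests."""
    return irai.build_array(8, 8, 3.45, 0.2, 0.35, 0.5)


@pytest.fixture(scope="session")
def single_element():
    return irai.build_array(1, 1, 3.45, 0.2, 0.35, 0.5)


@pytest.fixture(scope="session")
def pulse():
    return irai.RadiationPulse()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sphere_pressure():
    """Uniform unit-pressure sphere, radius 5 mm, centred 100 mm on axis.

    0.5 mm voxels (radius / 10) with an edge-antialiased mask; the
    matching source regularisation width (one voxel) is returned so the
    oracle can compare against the correspondingly regularised closed
    form.
    """
    a = 5.0
    spacing = 0.5
    grid = irai.Grid3D.from_extent((-6, 6), (-6, 6), (94, 106), spacing)
    gx, gy, gz = grid.meshgrid()
    r = np.sqrt(gx**2 + gy**2 + (gz - 100.0) ** 2)
    p0 = np.clip((a - r) / spacing + 0.5, 0.0, 1.0)
    return irai.PressureVolume(grid=grid, p0=p0), a, spacing
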
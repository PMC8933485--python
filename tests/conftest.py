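import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from phantomrad import PhantomSpec, generate_phantom, hu_to_mu
from phantomrad.geometry import build_circular_geometry, build_fan_geometry
from phantomrad.projection import Grid, get_projector


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_phantom():
    """64x64 single-slice phantom with all six ROIs (2D fast mode)."""
    spec = PhantomSpec.default(shape=(64, 64, 1), seed=1)
    volume, masks = generate_phantom(spec)
    return spec, volume, masks


@pytest.fixture(scope="session")
def fan_geometry_300():
    return build_fan_geometry(300)


@pytest.fixture(scope="session")
def tiny_projector():
    """8^3 grid / 4-view cone-beam instance, small enough to densify."""
    geometry = build_circular_geometry(4, detector=(8, 8, 4.0))
    grid = Grid((8, 8, 8), (2.0, 2.0, 2.0), (-8.0, -8.0, -8.0))
    return geometry, grid, get_projector(geometry, grid)
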
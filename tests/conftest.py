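"""Shared fixtures: canonical phantom geometry, orientation, tensor field."""

import numpy as np
import pytest

from cdtikit import phantom


@pytest.fixture(scope="session")
def geometry():
    """128x128 annulus used by the geometry-level tests."""
    return phantom.make_lv_geometry((128, 128), (63.5, 63.5), 15.0, 40.0)


@pytest.fixture(scope="session")
def small_geometry():
    """64x64 annulus matching the experiment's phantom scale."""
    return phantom.make_lv_geometry((64, 64), (31.5, 31.5), 9.0, 20.0)


@pytest.fixture(scope="session")
def orientation(small_geometry):
    return phantom.prescribe_orientation(small_geometry, 60.0, -60.0, 20.0)


@pytest.fixture(scope="session")
def tensor_field(orientation):
    return phantom.build_tensor_field(orientation, 1.0e-3, 0.45)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
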
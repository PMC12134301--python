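"""Shared fixtures: phantoms and reduced-resolution beam geometries."""

import numpy as np
import pytest

import kvtrack as kt
from kvtrack.projection import desk_geometry


@pytest.fixture(scope="session")
def phantom():
    """Standard 64^3 digital pelvis (no markers) and its prostate contour."""
    ct, contour, markers = kt.generate_phantom(kt.default_spec(), seed=1)
    return ct, contour, markers


@pytest.fixture(scope="session")
def marker_phantom():
    """Digital pelvis with three fiducial markers inside the prostate."""
    spec = kt.default_spec(with_markers=True)
    ct, contour, markers = kt.generate_phantom(spec, seed=1)
    return ct, contour, markers, spec


@pytest.fixture(scope="session")
def geom64():
    """64 x 64 detector covering the full clinical panel field of view."""
    return desk_geometry(64)


@pytest.fixture(scope="session")
def geom32():
    return desk_geometry(32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
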
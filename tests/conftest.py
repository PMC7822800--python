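import numpy as np
import pytest

from dosekit import (
    BeamSetup,
    Spectrum,
    build_material_library,
    make_analytic_spectrum,
    make_head_phantom,
)


@pytest.fixture(scope="session")
def lib():
    return build_material_library()


@pytest.fixture(scope="session")
def spectrum_120():
    return make_analytic_spectrum(120.0, filtration_mm=0.9)


@pytest.fixture(scope="session")
def head64():
    return make_head_phantom(64, 8, (1.0, 1.0, 5.0), seed=0)


@pytest.fixture(scope="session")
def head_setup(spectrum_120):
    """Beam collimated to the interior of the 64-voxel head phantom."""
    return BeamSetup(primary_angle=0.0, sod=800.0, sid=1200.0,
                     opening_phi=1.2, opening_theta=0.9, spectrum=spectrum_120)


@pytest.fixture
def mono60():
    return Spectrum(np.array([60.0]), np.array([1.0]), kvp=60.0)
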
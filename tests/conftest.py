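import numpy as np
import pytest

from skinbis import (
    ElectrodeArray,
    MeshResolution,
    default_skin_stack,
)
from skinbis.drt import synthesize_rc_spectrum


@pytest.fixture(scope="session")
def stack():
    return default_skin_stack()


@pytest.fixture(scope="session")
def array():
    return ElectrodeArray()


@pytest.fixture(scope="session")
def coarse_resolution():
    """Cheap discretization for tests that only exercise contracts."""
    return MeshResolution(elements_per_electrode=4, elements_per_gap=2,
                         layer_rows=(2, 3, 5, 4), growth=1.8)


@pytest.fixture(scope="session")
def debye_spectrum():
    """Noise-free single-Debye fixture: R_inf=10, R_p=5, tau=1e-4 s, 40 pts / 4 decades."""
    fc = 1.0 / (2 * np.pi * 1e-4)
    f = np.logspace(np.log10(fc) - 2, np.log10(fc) + 2, 40)
    return synthesize_rc_spectrum([(5.0, 1e-4)], 10.0, f)


@pytest.fixture(scope="session")
def two_debye_spectrum():
    """Two Debye elements with relaxation times separated by three decades."""
    return synthesize_rc_spectrum(
        [(5.0, 1e-5), (8.0, 1e-2)], 10.0, np.logspace(0, 6, 60)
    )
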
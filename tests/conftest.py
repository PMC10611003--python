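import numpy as np
import pytest

from phantomlight import DetectionAperture, build_lut
from phantomlight.pipeline_io import load_reference_phantoms


@pytest.fixture(scope="session")
def table1():
    """The bundled six-phantom reference set at the default anisotropy."""
    return load_reference_phantoms()


@pytest.fixture(scope="session")
def aperture_na08():
    return DetectionAperture(na=0.8)


@pytest.fixture(scope="session")
def default_lut():
    """31x31 deterministic forward LUT over mus' in [2,5], mua in [1e-3,1e-1].

    Built once per session with the P_N engine at d = 1 mm, g = 0.6,
    n = 1.552 in air; shared by the inversion round-trip tests.
    """
    return build_lut(
        np.linspace(2.0, 5.0, 31),
        np.geomspace(1e-3, 1e-1, 31),
        (0.6, 1.552, 1.0, 1.0),
        engine="pn",
    )
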
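import pytest

from gepi_screen.sequence_io import load_reference_isolates
from gepi_screen.synthetic_data import coil_trajectory, ideal_helix

DBAD1 = "STEARATTLTACDAY"
AL_S1 = "VPSSGPQDTRTT"


@pytest.fixture(scope="session")
def reference_table():
    """The 17 round-4 aluminum-binding isolates with multiplicities."""
    return load_reference_isolates()


@pytest.fixture(scope="session")
def poly_ser_helix():
    return ideal_helix("S" * 15)


@pytest.fixture(scope="session")
def dbad1_coil():
    """Random-coil null ensemble of the dominant isolate (seed frozen)."""
    return coil_trajectory(DBAD1, 200, seed=3)
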
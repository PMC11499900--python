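import numpy as np
import pytest

from aaapiv.geometry import IdealizedAAAGeometry
from aaapiv.workflows import Roi1Result, run_roi1_case

#: evenly spaced subset of the 25 acquisition phases used by the slower
#: end-to-end tests (full cycles are exercised by the acceptance script)
TEST_PHASES = [0, 3, 6, 9, 12, 15, 18, 21]


@pytest.fixture(scope="session")
def chain_phases() -> list[int]:
    return TEST_PHASES


@pytest.fixture(scope="session")
def default_geometry() -> IdealizedAAAGeometry:
    return IdealizedAAAGeometry()


@pytest.fixture(scope="session")
def fh_chain_result() -> Roi1Result:
    """Full synthetic FH/C4 chain on a phase subset, shared across tests."""
    return run_roi1_case("FH", "C4", seed=11, phases=TEST_PHASES)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
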
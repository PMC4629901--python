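import pathlib
import sys

import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from anisoblock.cell import CellConditions, equilibrate


@pytest.fixture(scope="session")
def normal_cond():
    return CellConditions()


@pytest.fixture(scope="session")
def normal_state(normal_cond):
    """50 s-equilibrated epicardial cell under normal conditions."""
    return equilibrate(normal_cond).state
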
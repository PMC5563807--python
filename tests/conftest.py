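import numpy as np
import pytest

from mortprof.io_model import default_scheme, demo_stage_map
from mortprof.reference_models import schematic_reference_set


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def stage_map(scheme):
    return demo_stage_map(scheme)


@pytest.fixture(scope="session")
def references(scheme):
    return schematic_reference_set(scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
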
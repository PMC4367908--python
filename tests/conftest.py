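import pytest

from vulvanet.dynamics import basin_summary, find_attractors
from vulvanet.model import build_wildtype_model


@pytest.fixture(scope="session")
def wildtype():
    return build_wildtype_model()


@pytest.fixture(scope="session")
def wildtype_attractors(wildtype):
    return find_attractors(wildtype)


@pytest.fixture(scope="session")
def wildtype_basins(wildtype, wildtype_attractors):
    return basin_summary(wildtype, wildtype_attractors)
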
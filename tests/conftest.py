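import pytest

from nbpool.tables import regenerate_table2


@pytest.fixture(scope="session")
def table2_regenerated():
    """The full 324-cell sample-size grid, regenerated once per session."""
    return regenerate_table2()


@pytest.fixture(scope="session")
def mc_seed():
    return 20120322
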
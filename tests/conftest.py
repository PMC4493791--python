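import pytest

from hd1panel.io import load_table1
from hd1panel.model import Region
from hd1panel.simulate import PanelConfig, simulate_panel


@pytest.fixture(scope="session")
def table1():
    """The packaged transcription of the published 44-accession panel."""
    return load_table1()


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated two-region panel shared by discovery/annotation tests."""
    config = PanelConfig(
        seed=5,
        n_accessions_per_region={Region.JAPAN: 6, Region.MAINLAND: 5},
    )
    return simulate_panel(config)
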
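import pytest

from gapstrat.calling import CallerConfig
from gapstrat.paper import load_cytobands, load_gene_catalog
from gapstrat.simulate import SimConfig


@pytest.fixture(scope="session")
def cytobands():
    return load_cytobands()


@pytest.fixture(scope="session")
def catalog(cytobands):
    return load_gene_catalog(cytobands)


@pytest.fixture
def caller_config():
    return CallerConfig()


@pytest.fixture
def small_genome_config():
    """Simulation restricted to the event-bearing chromosomes, for speed."""
    return SimConfig(chromosomes=("1", "4", "7", "12"))
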
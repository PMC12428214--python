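import pytest

from spliceomir.synthetic_data import SimulationConfig, make_planted_locus


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def planted(default_config):
    """(genomes, transcripts, loci, truth) for the default planted locus."""
    return make_planted_locus(default_config)
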
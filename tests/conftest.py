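import pytest

from cottonprx import synthetic_data as sd
from cottonprx.promoter_cis import load_catalogue


@pytest.fixture(scope="session")
def config():
    return sd.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def canonical_proteins(config):
    """Canonical fixture proteins and their truth table."""
    return sd.gen_proteins(config)


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def prx14_locus():
    return sd.gen_prx14_locus()
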
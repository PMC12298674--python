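import pytest

from polysplice.event_catalog import enumerate_events
from polysplice.psi_quant import compute_psi
from polysplice.synthetic_data import SimConfig, simulate, write_fixture_bundle


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic dataset (seed 1): 32 planted events per
    gained/lost/DAS/stable category, 60 planted DEGs, planted bias shifts."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_catalog(default_sim):
    return enumerate_events(default_sim.genes)


@pytest.fixture(scope="session")
def default_psi(default_sim, default_catalog):
    return compute_psi(default_catalog, default_sim.abundance)


@pytest.fixture(scope="session")
def fixture_dir(default_sim, tmp_path_factory):
    """The default dataset written to disk as a fixture bundle."""
    d = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(default_sim, d)
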
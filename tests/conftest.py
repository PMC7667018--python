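import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

from mitocomp.annotation import load_perisesarma_bidens
from mitocomp.gene_order import order_from_annotation
from mitocomp.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def pbidens_table():
    """The packaged published annotation summary (38 features, 15,641 bp)."""
    return load_perisesarma_bidens()


@pytest.fixture(scope="session")
def pbidens_order(pbidens_table):
    return order_from_annotation(pbidens_table)


@pytest.fixture(scope="session")
def sim42():
    """One default synthetic mitogenome, shared across tests."""
    return simulate_genome(SimulationConfig(seed=42))
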
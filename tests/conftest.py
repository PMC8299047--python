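import pytest

from melamap.synthetic import SimConfig, gen_toy_proteome


@pytest.fixture(scope="session")
def toy_proteome():
    """Six-protein toy proteome with the driver-mutation panel."""
    proteins, panel = gen_toy_proteome(seed=0)
    return proteins, panel


@pytest.fixture(scope="session")
def by_gene(toy_proteome):
    proteins, _ = toy_proteome
    return {p.gene: p for p in proteins}


@pytest.fixture(scope="session")
def small_config():
    """Fast abundance-simulation config for unit tests."""
    return SimConfig(n_proteins=300, n_batches=3, samples_per_batch=8,
                     n_reference=12, seed=7)
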
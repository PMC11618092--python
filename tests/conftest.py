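import numpy as np
import pytest

from crossleaf.simulate import (
    SimConfig,
    simulate_expression,
    simulate_regulatory_landscape,
)


@pytest.fixture(scope="session")
def small_sim():
    """A compact two-species simulation shared across tests."""
    cfg = SimConfig(seed=11, n_genes_per_species=150)
    adata_a, adata_b, orthology, truth = simulate_expression(cfg)
    return cfg, adata_a, adata_b, orthology, truth


@pytest.fixture(scope="session")
def small_landscape(small_sim):
    cfg, adata_a, adata_b, orthology, truth = small_sim
    return simulate_regulatory_landscape(cfg, truth, adata_a, adata_b)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
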
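import numpy as np
import pytest

from tenest.synthetic_data import SimulationConfig, make_v1_v2_locus, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated genome shared across read-only tests."""
    cfg = SimulationConfig(seed=11, chrom_len=150_000, n_host_te=12,
                           n_guest_te=12, n_genes=2)
    genome, repeats, genes, truth = simulate(cfg)
    return cfg, genome, repeats, genes, truth


@pytest.fixture(scope="session")
def v1v2_locus():
    return make_v1_v2_locus(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
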
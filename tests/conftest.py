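import numpy as np
import pytest

from dmgcn import PreprocessConfig, SimConfig, filter_and_normalize, simulate_dataset


@pytest.fixture(scope="session")
def tiny_sim():
    """Small planted-domain dataset shared across read-only tests."""
    cfg = SimConfig(
        n_rows=8, n_cols=8, n_domains=3, n_genes=40,
        n_marker_genes_per_domain=8, seed=3,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_pp(tiny_sim):
    return filter_and_normalize(tiny_sim, PreprocessConfig(min_cells=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
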
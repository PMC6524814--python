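import numpy as np
import pytest

from omnifisher.simulate import PoolConfig, build_pools


@pytest.fixture(scope="session")
def pools():
    """Default feature pools, shared across tests (seed-fixed)."""
    return build_pools(seed=1234)


@pytest.fixture(scope="session")
def small_pools():
    """Down-scaled pools for tests that only need structure, not size."""
    cfg = PoolConfig(n_haplotypes=2000, n_snp_sites=120, methyl_samples=200,
                     methyl_sites=100, expr_samples=80, expr_genes=40)
    return build_pools(cfg, seed=99)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
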
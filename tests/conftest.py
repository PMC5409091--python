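import numpy as np
import pytest

from cceqtl import SimulationConfig, simgen


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_panel():
    """400 individuals x 50 SNPs with moderate LD, reused across tests."""
    cfg = SimulationConfig(
        seed=77, n_individuals=400, n_snps=50, ld_decay=0.8,
        maf_range=(0.2, 0.5),
    )
    return simgen.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def tight_ld_panel():
    """Panel whose LD target is achievable (narrow MAFs, strong decay)."""
    cfg = SimulationConfig(
        seed=78, n_individuals=400, n_snps=50, ld_decay=0.95,
        maf_range=(0.25, 0.4),
    )
    return simgen.simulate_genotypes(cfg)
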
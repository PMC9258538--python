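import numpy as np
import pytest

import panelgwas as pg


@pytest.fixture(scope="session")
def small_panel():
    """A small panel with LD blocks and 3-group structure (deterministic)."""
    cfg = pg.SimulationConfig(
        n_genotypes=120, n_snps=600, n_chromosomes=3, seed=101
    )
    return pg.simulate_genotypes(cfg), cfg


@pytest.fixture(scope="session")
def small_trial(small_panel):
    geno, cfg = small_panel
    pheno, truth = pg.simulate_trial(geno, cfg)
    return geno, pheno, truth


@pytest.fixture(scope="session")
def kinship(small_panel):
    geno, _ = small_panel
    return pg.kinship_additive(geno, ld_prune_r2=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_601)
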
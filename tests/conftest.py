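import numpy as np
import pytest

from epiqtl.cohort import simulate_cohort, simulate_genotypes
from epiqtl.modality import MCMCSettings


@pytest.fixture(scope="session")
def small_genotypes():
    return simulate_genotypes(n_samples=120, n_variants=80, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(
        n_samples=120,
        n_expression_samples=80,
        n_eqtm_overlap=74,
        n_variants=150,
        n_genes=40,
        n_cpgs=80,
        n_planted_eqtl=8,
        n_planted_mqtl=10,
        gap_fraction=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced sampler settings for unit tests."""
    return MCMCSettings(n_iter=1500, burn_in=400)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
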
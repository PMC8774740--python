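import numpy as np
import pytest

from poefam.simulate import SimulationConfig, simulate_families


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-family fully genotyped cohort with a modest paternal effect."""
    cfg = SimulationConfig(
        seed=7,
        n_families=60,
        beta_pat={"snp1": 0.4},
        geno_missing_rate=0.0,
        parent_missing_rate=0.0,
        pheno_missing_rate=0.0,
    )
    return simulate_families(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
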
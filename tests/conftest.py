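import numpy as np
import pytest

from gwexpand import DiseaseModel, SimulationConfig, simulate_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """Miniature study: fast enough for per-test pipelines."""
    return SimulationConfig(
        n_cases=30, n_controls=30, external_cohort_sizes=(30,),
        n_null_snps=500, fst=(0.1,), seed=11,
    )


@pytest.fixture(scope="session")
def small_replicate(small_config):
    return simulate_replicate(small_config)


@pytest.fixture(scope="session")
def two_pop_replicate():
    """100+100 source samples vs one diverged cohort at Fst 0.1, 10k SNPs."""
    cfg = SimulationConfig(
        n_cases=50, n_controls=50, external_cohort_sizes=(100,),
        n_null_snps=10_000, fst=(0.1,), seed=5,
    )
    return simulate_replicate(cfg)


@pytest.fixture(scope="session")
def power_model():
    return DiseaseModel(prevalence=0.001, het_grr=1.5, risk_allele_freq=0.2)
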
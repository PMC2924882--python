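import numpy as np
import pytest

from cnvassoc.simulate import CnvRegion, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """50 cases / 50 controls, 120 SNPs, one planted deletion (raw intensities)."""
    config = SimulationConfig(
        n_cases=50,
        n_controls=50,
        n_snps_per_chrom=120,
        n_chromosomes=1,
        cnv_regions=[
            CnvRegion("1", 50, 8, 1, control_freq=0.05, case_freq=0.30),
            CnvRegion("1", 90, 10, 3, control_freq=0.10, case_freq=0.10),
        ],
        seed=11,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def null_signals_cohort():
    """Label-exchangeable cohort in shortcut (LRR/BAF) mode."""
    config = SimulationConfig(
        n_cases=60,
        n_controls=60,
        n_snps_per_chrom=150,
        cnv_regions=[
            CnvRegion("1", 30, 8, 1, control_freq=0.15, case_freq=0.15),
            CnvRegion("1", 80, 12, 3, control_freq=0.20, case_freq=0.20),
        ],
        seed=7,
    )
    return simulate_cohort(config, raw=False)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
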
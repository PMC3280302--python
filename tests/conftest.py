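import numpy as np
import pytest

from bmilong.association import stratum_table
from bmilong.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no genetic effects (shared across read-only tests)."""
    cfg = SimulationConfig(n_subjects=120, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with one strong additive SNP effect on BMI."""
    cfg = SimulationConfig(n_subjects=658, seed=7,
                           snp_effects={"rs8050136": 0.8})
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def child_table(null_cohort):
    cohort, phen = null_cohort
    return stratum_table(cohort, phen, "child")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
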
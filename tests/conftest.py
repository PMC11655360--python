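import numpy as np
import pytest

from bwasdesign import ModelSpec, SimConfig, simulate_longitudinal_study
from bwasdesign.cohort import CROSS_SECTIONAL, LONGITUDINAL


@pytest.fixture(scope="session")
def cross_sectional_cohort():
    """Moderate cross-sectional cohort with a real covariate effect."""
    cfg = SimConfig(
        n_subjects=600,
        visits_per_subject=1,
        beta_between=0.4,
        beta_within=0.4,
        covariate_between_sd=1.0,
        covariate_within_sd=0.0,
        subject_intercept_sd=0.8,
        seed=101,
    )
    return simulate_longitudinal_study(cfg)


@pytest.fixture(scope="session")
def longitudinal_cohort():
    """Three-visit longitudinal cohort with equal between/within effects."""
    cfg = SimConfig(
        n_subjects=400,
        visits_per_subject=3,
        beta_between=0.35,
        beta_within=0.35,
        covariate_between_sd=1.0,
        covariate_within_sd=0.6,
        subject_intercept_sd=1.0,
        seed=202,
    )
    return simulate_longitudinal_study(cfg)


@pytest.fixture(scope="session")
def cs_spec():
    return ModelSpec.from_formula("y ~ ns(age, df=2) + sex + x", design=CROSS_SECTIONAL)


@pytest.fixture(scope="session")
def long_spec():
    return ModelSpec.from_formula("y ~ ns(age, df=2) + sex + x", design=LONGITUDINAL)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
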
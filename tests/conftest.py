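import numpy as np
import pandas as pd
import pytest

from qolnorm.cohort import TruthConfig, generate_cohort, inject_missingness
from qolnorm.scoring import TariffTable, TransformSpec


@pytest.fixture(scope="session")
def toy_tariff() -> TariffTable:
    """Tiny hand-checkable tariff: constant 0.10 plus one mobility decrement."""
    return TariffTable(
        decrements={
            ("mobility", 2): 0.05,
            ("mobility", 3): 0.30,
            ("self_care", 2): 0.04,
            ("self_care", 3): 0.20,
            ("usual_activities", 2): 0.03,
            ("usual_activities", 3): 0.10,
            ("pain_discomfort", 2): 0.06,
            ("pain_discomfort", 3): 0.25,
            ("anxiety_depression", 2): 0.02,
            ("anxiety_depression", 3): 0.12,
        },
        any_problem=0.10,
    )


#: reduced generating truth used across recovery-style tests: age profile plus
#: two real determinants for each submodel, everything else zero
REDUCED_NU = {
    "intercept": 1.0,
    "age": 0.04,
    "age2": -0.0007,
    "exp_severe_self": -1.0,
    "pets": -0.4,
}
REDUCED_MU = {"intercept": 2.0, "age": -0.02, "exp_severe_self": -0.3, "pets": -0.2}


def reduced_truth(n=2000, seed=0) -> TruthConfig:
    return TruthConfig(n=n, nu_coefs=dict(REDUCED_NU), mu_coefs=dict(REDUCED_MU), seed=seed)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Complete synthetic cohort, n=1500, default (survey-like) truth."""
    return generate_cohort(TruthConfig(n=1500), seed=42)


@pytest.fixture(scope="session")
def small_cohort_missing(small_cohort) -> pd.DataFrame:
    return inject_missingness(small_cohort, seed=43)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def eq5d_spec() -> TransformSpec:
    """Transform spec matching the generator's index range."""
    return TransformSpec(n=1500, min_index=-0.074, max_index=0.817)
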
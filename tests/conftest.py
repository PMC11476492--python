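import numpy as np
import pandas as pd
import pytest

from perisk.cohort import CohortSpec, TransferParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Small labelled cohort with ~25% missingness, shared across tests."""
    spec = CohortSpec(n_cases=30, n_controls=90, missing_rate=0.25, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def complete_cohort() -> pd.DataFrame:
    """Cohort without any missing entries."""
    spec = CohortSpec(n_cases=25, n_controls=75, missing_rate=0.0, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_spec() -> CohortSpec:
    """Spec with exact dependent-pair relations (no residual noise)."""
    return CohortSpec(
        n_cases=60,
        n_controls=140,
        missing_rate=0.0,
        pair_noise_sd=0.0,
        transfer_params=TransferParams(noise_sd=0.0),
        seed=5,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
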
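import numpy as np
import pandas as pd
import pytest

from tziprisk import CovariateSpec, generate_cohort, reference_params
from tziprisk.tzip import fit_tzip


@pytest.fixture(scope="session")
def ref_params():
    return reference_params()


@pytest.fixture(scope="session")
def small_cohort(ref_params):
    """4,000 episodes with service features: enough signal for smoke-level fits."""
    spec = CovariateSpec(n_service_features=6, residential_fraction=0.4)
    return generate_cohort(4_000, ref_params, spec, seed=11)


@pytest.fixture(scope="session")
def small_fit(small_cohort, ref_params):
    return fit_tzip(small_cohort, families=ref_params.family)


@pytest.fixture(scope="session")
def big_cohort(ref_params):
    """50,000 episodes at default study conditions (shared across MC checks)."""
    return generate_cohort(50_000, ref_params, CovariateSpec(), seed=0)


@pytest.fixture(scope="session")
def big_fit(big_cohort, ref_params):
    return fit_tzip(big_cohort, families=ref_params.family)


@pytest.fixture()
def toy_episodes():
    """Hand-sized episode table with explicit event times."""
    return pd.DataFrame(
        {
            "episode_id": [f"e{i}" for i in range(6)],
            "patient_id": [f"p{i}" for i in range(6)],
            "discharge_day": [0, 30, 60, 90, 300, 330],
            "los_days": [2.0, 5.0, 1.0, 8.0, 3.0, 20.0],
            "acute_admission": [1, 0, 1, 1, 0, 1],
            "charlson_index": [0, 2, 1, 4, 0, 6],
            "er_visits_6m": [0, 1, 0, 2, 0, 9],
            "exposure_days": [400.0, 500.0, 365.0, 600.0, 700.0, 728.0],
            "rehosp_count": [0, 2, 1, 0, 3, 0],
            "event_days": [
                np.empty(0),
                np.array([10.0, 200.0]),
                np.array([50.0]),
                np.empty(0),
                np.array([30.0, 31.0, 600.0]),
                np.empty(0),
            ],
            "residence": ["community"] * 6,
        }
    )
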
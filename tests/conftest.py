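import numpy as np
import pandas as pd
import pytest

from cohortweights import CohortConfig, generate_cohort
from cohortweights.synthetic import derive_census_margins


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_population=4000, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_margins(small_config) -> pd.DataFrame:
    return derive_census_margins(small_config, inflation=10.0)


def saturated_cells():
    """Deterministic 4-cell (sex × index status) selection layout used by
    the saturated-model oracle tests: per cell, exact counts of
    envisioned, responders, timely responders and (re)infected."""
    return [
        # (sex, index, envisioned, responded, timely, reinfected)
        ("Female", "Negative", 120, 30, 24, 4),
        ("Female", "Positive", 80, 20, 15, 5),
        ("Male", "Negative", 100, 25, 20, 2),
        ("Male", "Positive", 60, 12, 9, 3),
    ]


@pytest.fixture(scope="session")
def saturated_cohort() -> pd.DataFrame:
    """Cohort whose sweep-12 selection counts are exact by construction
    (first k persons of each cell respond, and so on down the nesting)."""
    rows = []
    pid = 0
    for sex, index, n_env, n_resp, n_timely, n_reinf in saturated_cells():
        for i in range(n_env):
            responded = i < n_resp
            timely = i < n_timely
            reinfected = i < n_reinf if timely else np.nan
            rows.append({
                "id": pid,
                "sex": sex,
                "index_status": index,
                "age_years": 14,
                "region": "London",
                "imd_decile": 5.0,
                "ethnicity": "White",
                "month_of_test": "2020-09",
                "contacted_6m": True,
                "available_12m": True,
                "responded_12m": float(responded),
                "weeks_12m": 50.0 if responded else np.nan,
                "timely_12m": float(timely) if responded else np.nan,
                "reinfected_12m": reinfected,
            })
            pid += 1
    return pd.DataFrame(rows)
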
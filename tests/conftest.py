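import numpy as np
import pandas as pd
import pytest

from fbgrisk.cohort import Cohort


@pytest.fixture
def toy_cohort() -> Cohort:
    """Three participants, hand-written visits and covariates."""
    visits = pd.DataFrame(
        {
            "participant_id": ["a"] * 3 + ["b"] * 4 + ["c"] * 3,
            "visit_time_days": [0, 400, 900, 0, 300, 700, 1100, 0, 500, 1000],
            "fbg_mmol_l": [5.0, 6.0, 7.0, 4.9, 5.3, 6.1, 7.9, 5.6, 5.6, 5.6],
        }
    )
    participants = pd.DataFrame(
        {
            "participant_id": ["a", "b", "c"],
            "age": [45.0, 52.0, 60.0],
            "female": [1.0, 0.0, 1.0],
            "education_low": [0.0, 1.0, 0.0],
            "income_low": [1.0, 1.0, 0.0],
            "current_smoking": [0.0, 1.0, 0.0],
            "current_drinking": [0.0, 1.0, 1.0],
            "bmi": [23.0, 27.5, 24.0],
            "hypertension": [0.0, 1.0, 0.0],
            "dyslipidemia": [1.0, 1.0, 0.0],
            "dr_status": [0.0, 1.0, 0.0],
            "has_final_window_fbg": [1, 1, 1],
        }
    )
    return Cohort(visits, participants)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130714)


def random_series(rng, n=None, tmax=3000.0):
    """A random strictly-increasing-time positive FBG series."""
    if n is None:
        n = int(rng.integers(3, 8))
    t = np.sort(rng.uniform(0, tmax, n))
    while len(np.unique(t)) < n:
        t = np.sort(rng.uniform(0, tmax, n))
    v = rng.uniform(3.5, 11.0, n)
    return t, v
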
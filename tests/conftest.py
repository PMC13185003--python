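import numpy as np
import pandas as pd
import pytest

from hbtraj.data_model import CohortData, preprocess, subset_by_visit_count
from hbtraj.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort from the generator defaults."""
    cohort, truth = simulate_cohort(SimConfig(n_subjects=1200, seed=101))
    return cohort, truth


@pytest.fixture(scope="session")
def three_visit_cohort():
    """Preprocessed all-3-visit cohort of 676 women (study subset size)."""
    cohort, truth = simulate_cohort(
        SimConfig(n_subjects=676, prop_three_visits=1.0, seed=202)
    )
    return subset_by_visit_count(preprocess(cohort), 3), truth


@pytest.fixture()
def tiny_cohort():
    """Hand-built 3-subject cohort for exact arithmetic checks."""
    visits = pd.DataFrame(
        {
            "subject_id": [1, 1, 1, 2, 2, 2, 2, 3, 3],
            "ga_weeks": [10.0, 24.0, 32.0, 9.0, 22.0, 26.0, 30.0, 11.0, 33.0],
            "hb_g_l": [120.0, 110.0, 112.0, 118.0, 110.0, 114.0, 111.0, 125.0, 119.0],
        }
    )
    outcomes = pd.DataFrame(
        {
            "subject_id": [1, 2, 3],
            "birthweight_g": [3100.0, 2400.0, np.nan],
            "ga_delivery_weeks": [39.0, 36.0, 37.0],
            "weight_percentile": [50.0, 8.0, 30.0],
        }
    )
    return CohortData(visits, outcomes)
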
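import numpy as np
import pandas as pd
import pytest

import dietchange as dc
from dietchange import instrument as ins


@pytest.fixture(scope="session")
def fct():
    return dc.generate_food_composition_table(0)


@pytest.fixture(scope="session")
def dii_ref():
    return dc.generate_dii_reference(0)


@pytest.fixture(scope="session")
def cohort():
    """Small violation-free paired-visit cohort."""
    return dc.generate_cohort(dc.SimulationConfig(n_subjects=300, seed=11))


@pytest.fixture(scope="session")
def processed(cohort, fct):
    return dc.process_records(cohort, fct)


def blank_record(sex="F", age_group=40, photo_level=2):
    """One subject-visit row with every item 'never' and valid photos."""
    row = {"subject_id": 1, "visit": 1, "sex": sex, "age_group": age_group,
           "age": float(age_group), "exam_date": "2000-06-15", "exam_year": 2000}
    for c in ins.PHOTO_COLUMNS:
        row[c] = float(photo_level)
    for c in ins.FFQ_COLUMNS:
        row[c] = 0.0
    return pd.DataFrame([row])


@pytest.fixture
def record():
    return blank_record()


@pytest.fixture
def flat_portions():
    """Portion model with unit sex/age factors for hand arithmetic."""
    return dc.PortionModel(
        sex_factor={"F": 1.0, "M": 1.0},
        age_factor={30: 1.0, 40: 1.0, 50: 1.0, 60: 1.0},
    )
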
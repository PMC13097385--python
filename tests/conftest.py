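"""Shared fixtures: small and study-scale synthetic cohorts.

All cohorts are generated at test time from frozen generator defaults;
the study-scale cohort (75 subjects, 40 % sarcopenia prevalence) is
session-scoped because downstream tests (features, cross-validation)
reuse it.
"""

import numpy as np
import pandas as pd
import pytest

from sarcoscreen.cohort import SimulationConfig, SubjectProfile, generate_cohort
from sarcoscreen.features import mvc_normalize, session_feature_table


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """8 subjects, balanced groups — cheap enough for unit tests."""
    return generate_cohort(n_subjects=8, prevalence=0.5, seed=3)


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale cohort: 75 subjects at 40 % prevalence, fixed seed."""
    return generate_cohort(n_subjects=75, prevalence=0.4, seed=11)


@pytest.fixture(scope="session")
def study_dataset(study_cohort):
    from sarcoscreen.model import build_dataset

    recordings, profiles = study_cohort
    return build_dataset(recordings, profiles)


@pytest.fixture(scope="session")
def study_feature_table(study_cohort):
    """MVC-normalized active-window features (BR sEMG) for the study cohort."""
    recordings, profiles = study_cohort
    tables = []
    for rec in recordings:
        t = session_feature_table(rec, channels=("br_semg",))
        tables.append(
            mvc_normalize(
                t[t["kind"] == "active"], reference_table=t[t["kind"] == "trial"]
            )
        )
    table = pd.concat(tables, ignore_index=True)
    labels = {p.subject_id: p.group_label for p in profiles}
    return table, labels


@pytest.fixture
def healthy_profile():
    return SubjectProfile(
        subject_id="H0", sex="male", age=70, grip_strength=36.0,
        smi=7.9, chair_stand_time=9.0, group_label="healthy",
    )


@pytest.fixture
def sarcopenic_profile():
    return SubjectProfile(
        subject_id="S0", sex="male", age=72, grip_strength=21.0,
        smi=6.2, chair_stand_time=13.0, group_label="sarcopenia",
    )
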
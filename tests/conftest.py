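from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pelandmark import synth
from pelandmark import trajectory as tj


@pytest.fixture(scope="session")
def small_bundle() -> synth.CohortBundle:
    """Moderate synthetic cohort shared across read-only tests."""
    return synth.simulate_cohort(synth.default_config(n_subjects=1500, seed=42))


@pytest.fixture(scope="session")
def small_models(small_bundle) -> dict[str, tj.TrajectoryModel]:
    nonpe = small_bundle.subjects[~small_bundle.subjects["pe"]]
    visits = small_bundle.visits[
        small_bundle.visits["subject_id"].isin(nonpe["subject_id"])
    ]
    return {
        m: tj.fit_population_trajectory(nonpe, visits, m)
        for m in ["sbp", "dbp", "weight", "hb", "sf_height"]
    }


def tiny_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two hand-written subjects (one case) with three visits."""
    subjects = pd.DataFrame(
        {
            "subject_id": pd.array(["A", "B"], dtype="string"),
            "maternal_age": [28.0, 33.5],
            "height_cm": [165.0, 172.0],
            "region_of_birth": ["Sweden", "Asia"],
            "family_situation": ["with_partner", "single"],
            "smoking_pre": ["none", "lt10"],
            "smoking_early": ["none", "none"],
            "prev_miscarriage": [False, True],
            "infertility_duration": ["none", "gt2"],
            "infertility_treatment": ["none", "ivf"],
            "fam_hist_preeclampsia": [False, True],
            "fam_hist_hypertension": [False, False],
            "cardiovascular_disease": [False, False],
            "endocrine_disease": [False, False],
            "preexisting_diabetes": [False, False],
            "thrombosis": [False, False],
            "sle": [False, False],
            "chronic_hypertension": [False, True],
            "ibd": [False, False],
            "chronic_kidney_disease": [False, False],
            "blood_group": ["O", "B"],
            "aspirin_use": [False, True],
            "pe": [False, True],
            "ga_diagnosis_days": [np.nan, 250.0],
            "ga_delivery_days": [280, 262],
        }
    )
    visits = pd.DataFrame(
        {
            "subject_id": pd.array(["A", "A", "B"], dtype="string"),
            "ga_days": [70, 180, 200],
            "sbp": [118.0, 114.0, 125.0],
            "dbp": [70.0, 66.0, 82.0],
            "weight": [64.0, 70.0, 71.5],
            "hb": [128.0, 119.0, 131.0],
            "sf_height": [np.nan, 25.0, 29.0],
            "glucose": [5.0, 5.4, 9.2],
            "proteinuria": [0.0, np.nan, 2.0],
        }
    )
    return subjects, visits


@pytest.fixture
def tiny():
    return tiny_cohort()
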
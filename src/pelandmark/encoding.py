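"""Deterministic dummy encoding of baseline covariates.

Reference levels are the largest category of each covariate in the study
population: Sweden for region of birth, living with partner, non-smoking,
no infertility, blood group O.  ``missing`` is its own dummy, never imputed.
Continuous covariates (maternal age, height) are centered at the cohort
reference values below so that the intercept is interpretable.

The same encoding is used by the synthetic generator's outcome model and by
the landmark risk models, so logistic coefficients are directly comparable
to the generating values in recovery studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pelandmark.cohort import BOOLEAN_SUBJECT_COLUMNS, CATEGORY_LEVELS

#: centering constants for the two continuous baseline covariates
AGE_CENTER = 29.3
HEIGHT_CENTER = 166.6

REFERENCE_LEVELS = {
    "region_of_birth": "Sweden",
    "family_situation": "with_partner",
    "smoking_pre": "none",
    "smoking_early": "none",
    "infertility_duration": "none",
    "infertility_treatment": "none",
    "blood_group": "O",
}

_BOOLEAN_PREDICTORS = [
    c for c in BOOLEAN_SUBJECT_COLUMNS if c not in ("aspirin_use", "pe")
]


def baseline_columns() -> list[str]:
    """Deterministic column order of the encoded baseline design."""
    cols = ["maternal_age_c", "height_cm_c"]
    for cat, ref in REFERENCE_LEVELS.items():
        cols += [f"{cat}={lv}" for lv in CATEGORY_LEVELS[cat] if lv != ref]
    cols += _BOOLEAN_PREDICTORS
    return cols


def encode_baseline(subjects: pd.DataFrame) -> pd.DataFrame:
    """Encode baseline covariates into the fixed-order design matrix.

    Returns a float DataFrame indexed by ``subject_id`` whose columns are
    :func:`baseline_columns`.
    """
    out = pd.DataFrame(index=pd.Index(subjects["subject_id"], name="subject_id"))
    out["maternal_age_c"] = subjects["maternal_age"].to_numpy() - AGE_CENTER
    out["height_cm_c"] = subjects["height_cm"].to_numpy() - HEIGHT_CENTER
    for cat, ref in REFERENCE_LEVELS.items():
        vals = subjects[cat].to_numpy()
        for lv in CATEGORY_LEVELS[cat]:
            if lv != ref:
                out[f"{cat}={lv}"] = (vals == lv).astype(float)
    for col in _BOOLEAN_PREDICTORS:
        out[col] = subjects[col].to_numpy().astype(float)
    assert list(out.columns) == baseline_columns()
    return out.astype(float)


def linear_predictor(
    subjects: pd.DataFrame, coefficients: dict[str, float], intercept: float = 0.0
) -> np.ndarray:
    """Evaluate ``intercept + X @ beta`` for a sparse coefficient dict."""
    design = encode_baseline(subjects)
    eta = np.full(len(design), float(intercept))
    for name, beta in coefficients.items():
        if name not in design.columns:
            raise KeyError(f"unknown baseline design column {name!r}")
        eta += beta * design[name].to_numpy()
    return eta
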
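"""Cohort schema, CSV readers/writers and validation.

A cohort is a pair of pandas DataFrames:

``subjects``
    one row per woman: baseline covariates recorded at the first antenatal
    visit, an aspirin-use flag, and the outcome (preeclampsia indicator with
    gestational ages, in days, at diagnosis and delivery).

``visits``
    one row per antenatal visit: gestational age in days plus any subset of
    the seven time-varying measurements (systolic/diastolic blood pressure,
    weight, hemoglobin in g/L, symphysis-fundal height, capillary glucose,
    proteinuria dipstick category).

Gestational age is stored in days throughout; "completed week w" means
``ga_days`` in ``[7w, 7w + 6]``.  Missing baseline categories are an explicit
``missing`` level, never imputed.  Optional visit measurements are blank cells
in CSV and NaN in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Schema

CATEGORY_LEVELS: dict[str, list[str]] = {
    "region_of_birth": [
        "Sweden",
        "Nordic_other",
        "Europe_other",
        "Africa",
        "North_America",
        "South_America",
        "Asia",
        "Oceania",
        "missing",
    ],
    "family_situation": ["single", "with_partner", "other", "missing"],
    "smoking_pre": ["none", "lt10", "ge10", "missing"],
    "smoking_early": ["none", "lt10", "ge10", "missing"],
    "infertility_duration": ["none", "y1_2", "gt2"],
    "infertility_treatment": ["none", "ovarian_stimulation", "ivf"],
    "blood_group": ["O", "A", "AB", "B", "missing"],
}

BOOLEAN_SUBJECT_COLUMNS = [
    "prev_miscarriage",
    "fam_hist_preeclampsia",
    "fam_hist_hypertension",
    "cardiovascular_disease",
    "endocrine_disease",
    "preexisting_diabetes",
    "thrombosis",
    "sle",
    "chronic_hypertension",
    "ibd",
    "chronic_kidney_disease",
    "aspirin_use",
    "pe",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "maternal_age",
    "height_cm",
    "region_of_birth",
    "family_situation",
    "smoking_pre",
    "smoking_early",
    "prev_miscarriage",
    "infertility_duration",
    "infertility_treatment",
    "fam_hist_preeclampsia",
    "fam_hist_hypertension",
    "cardiovascular_disease",
    "endocrine_disease",
    "preexisting_diabetes",
    "thrombosis",
    "sle",
    "chronic_hypertension",
    "ibd",
    "chronic_kidney_disease",
    "blood_group",
    "aspirin_use",
    "pe",
    "ga_diagnosis_days",
    "ga_delivery_days",
]

#: continuous markers measured repeatedly (hemoglobin in g/L)
CONTINUOUS_MARKERS = ["sbp", "dbp", "weight", "hb", "sf_height"]

VISIT_COLUMNS = [
    "subject_id",
    "ga_days",
    "sbp",
    "dbp",
    "weight",
    "hb",
    "sf_height",
    "glucose",
    "proteinuria",
]

#: earliest delivery included (22 completed weeks)
MIN_DELIVERY_DAYS = 154
#: preeclampsia is defined after 20 weeks' gestation
MIN_DIAGNOSIS_DAYS = 140
#: symphysis-fundal height is measured from gestational week 24
SF_HEIGHT_MIN_DAYS = 168


class CohortLoadError(ValueError):
    """Raised when a cohort CSV cannot be parsed into the declared schema."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_cohort`.

    ``violations`` holds one ``(rule_id, subject_id, message)`` triple per
    broken invariant; an empty list means the cohort passes every check.
    """

    n_subjects: int
    n_visits: int
    violations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# Readers / writers


def _check_categories(df: pd.DataFrame, path: str) -> None:
    for col, levels in CATEGORY_LEVELS.items():
        vals = df[col].astype("string")
        bad = ~vals.isin(levels) & vals.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortLoadError(
                f"{path} row {row + 2}: unknown {col} level {vals.iloc[row]!r}"
            )


def load_cohort(
    subjects_path: str | Path, visits_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and type a cohort from ``subjects.csv`` / ``visits.csv``.

    Booleans are encoded 0/1, categories as their level names and optional
    measurements as blank cells.  Unknown columns, unparseable numbers,
    unknown category levels and visits referencing unknown subjects raise
    :class:`CohortLoadError` naming the offending row.
    """
    subjects_path, visits_path = Path(subjects_path), Path(visits_path)
    try:
        subjects = pd.read_csv(subjects_path, dtype={"subject_id": "string"})
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise CohortLoadError(f"{subjects_path}: {exc}") from exc
    if list(subjects.columns) != SUBJECT_COLUMNS:
        raise CohortLoadError(
            f"{subjects_path}: columns {list(subjects.columns)} != expected "
            f"{SUBJECT_COLUMNS}"
        )
    _check_categories(subjects, str(subjects_path))
    for col in ["maternal_age", "height_cm", "ga_diagnosis_days", "ga_delivery_days"]:
        try:
            subjects[col] = pd.to_numeric(subjects[col])
        except (ValueError, TypeError) as exc:
            raise CohortLoadError(f"{subjects_path}: column {col}: {exc}") from exc
    for col in BOOLEAN_SUBJECT_COLUMNS:
        vals = pd.to_numeric(subjects[col], errors="coerce")
        if not vals.isin([0, 1]).all():
            row = int(np.flatnonzero(~vals.isin([0, 1]).to_numpy())[0])
            raise CohortLoadError(
                f"{subjects_path} row {row + 2}: column {col} must be 0/1"
            )
        subjects[col] = vals.astype(bool)

    try:
        visits = pd.read_csv(visits_path, dtype={"subject_id": "string"})
    except ValueError as exc:  # pragma: no cover
        raise CohortLoadError(f"{visits_path}: {exc}") from exc
    if list(visits.columns) != VISIT_COLUMNS:
        raise CohortLoadError(
            f"{visits_path}: columns {list(visits.columns)} != expected {VISIT_COLUMNS}"
        )
    for col in VISIT_COLUMNS[1:]:
        try:
            visits[col] = pd.to_numeric(visits[col])
        except (ValueError, TypeError) as exc:
            raise CohortLoadError(f"{visits_path}: column {col}: {exc}") from exc
    prot = visits["proteinuria"]
    bad = prot.notna() & ~prot.isin([0, 1, 2])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortLoadError(
            f"{visits_path} row {row + 2}: proteinuria {prot.iloc[row]!r} not in 0/1/2"
        )
    unknown = ~visits["subject_id"].isin(subjects["subject_id"])
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise CohortLoadError(
            f"{visits_path} row {row + 2}: unknown subject_id "
            f"{visits['subject_id'].iloc[row]!r}"
        )
    return subjects, visits


def write_cohort(
    subjects: pd.DataFrame, visits: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``subjects.csv`` and ``visits.csv``; inverse of :func:`load_cohort`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spath, vpath = out_dir / "subjects.csv", out_dir / "visits.csv"

    s = subjects[SUBJECT_COLUMNS].copy()
    for col in BOOLEAN_SUBJECT_COLUMNS:
        s[col] = s[col].astype(int)
    s.to_csv(spath, index=False)

    v = visits[VISIT_COLUMNS].copy()
    v.to_csv(vpath, index=False)
    return spath, vpath


# ---------------------------------------------------------------------------
# Validation


def validate_cohort(subjects: pd.DataFrame, visits: pd.DataFrame) -> ValidationReport:
    """Check every schema invariant; violations are data, not exceptions."""
    report = ValidationReport(n_subjects=len(subjects), n_visits=len(visits))
    add = report.violations.append

    if subjects["subject_id"].duplicated().any():
        for sid in subjects.loc[subjects["subject_id"].duplicated(), "subject_id"]:
            add(("unique_subject_id", str(sid), "duplicate subject_id"))

    for _, s in subjects.iterrows():
        sid = str(s["subject_id"])
        if s["ga_delivery_days"] < MIN_DELIVERY_DAYS:
            add(
                (
                    "delivery_ge_22w",
                    sid,
                    f"ga_delivery_days={s['ga_delivery_days']} < {MIN_DELIVERY_DAYS}",
                )
            )
        if s["pe"]:
            if pd.isna(s["ga_diagnosis_days"]):
                add(("pe_needs_dx_ga", sid, "pe without ga_diagnosis_days"))
            else:
                if s["ga_diagnosis_days"] <= MIN_DIAGNOSIS_DAYS:
                    add(
                        (
                            "dx_after_20w",
                            sid,
                            f"ga_diagnosis_days={s['ga_diagnosis_days']} <= "
                            f"{MIN_DIAGNOSIS_DAYS}",
                        )
                    )
                if s["ga_diagnosis_days"] > s["ga_delivery_days"]:
                    add(("dx_before_delivery", sid, "diagnosis after delivery"))
        elif not pd.isna(s["ga_diagnosis_days"]):
            add(("dx_only_if_pe", sid, "ga_diagnosis_days present without pe"))

    delivery = subjects.set_index("subject_id")["ga_delivery_days"]
    vdel = visits["subject_id"].map(delivery)
    for idx in np.flatnonzero(visits["ga_days"].to_numpy() < 0):
        add(("ga_nonneg", str(visits["subject_id"].iloc[idx]), "ga_days < 0"))
    late = visits["ga_days"] > vdel
    for idx in np.flatnonzero(late.to_numpy()):
        add(
            (
                "visit_before_delivery",
                str(visits["subject_id"].iloc[idx]),
                f"visit at {visits['ga_days'].iloc[idx]} after delivery",
            )
        )
    early_sf = visits["sf_height"].notna() & (visits["ga_days"] < SF_HEIGHT_MIN_DAYS)
    for idx in np.flatnonzero(early_sf.to_numpy()):
        add(
            (
                "sf_from_24w",
                str(visits["subject_id"].iloc[idx]),
                f"sf_height at ga_days={visits['ga_days'].iloc[idx]} < "
                f"{SF_HEIGHT_MIN_DAYS}",
            )
        )
    sbp, dbp = visits["sbp"], visits["dbp"]
    bad_bp = (sbp.notna() & dbp.isna()) | (sbp.notna() & dbp.notna() & (sbp <= dbp))
    for idx in np.flatnonzero(bad_bp.to_numpy()):
        add(
            (
                "bp_pair",
                str(visits["subject_id"].iloc[idx]),
                "sbp without dbp or sbp <= dbp",
            )
        )
    return report
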
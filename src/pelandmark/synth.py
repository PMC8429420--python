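"""Seeded synthetic antenatal cohort generator.

Emulates the statistical structure of a Swedish nulliparous antenatal-care
cohort: ~4.4% preeclampsia incidence, a first visit around gestational week
10 followed by roughly monthly visits that become weekly near term (median 11
visits without and 12 with preeclampsia), five continuous markers whose
population mean curves show the characteristic second-trimester dip in blood
pressure and hemoglobin, preeclampsia-dependent trajectory departures that
ramp up before diagnosis (concentrated in curvature by default), and excess
high capillary glucose and dipstick proteinuria among cases.

The outcome is assigned by a logistic model on the encoded baseline
covariates, with the intercept solved numerically so the realized marginal
incidence matches the configured target.  Visits after diagnosis are still
generated until delivery: diagnosed women are removed later by the landmark
risk-set rule, not by the generator.

All randomness flows through a single :class:`numpy.random.Generator`
(PCG64), so output is bit-reproducible for a given seed on any platform.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
import yaml
from numpy.polynomial import polynomial as npoly
from scipy.optimize import brentq
from scipy.special import expit

from pelandmark import cohort as cm
from pelandmark.encoding import linear_predictor

# ---------------------------------------------------------------------------
# Configuration


def _cubic_through(points: list[tuple[float, float]]) -> list[float]:
    """Ascending coefficients of the cubic interpolating four (ga, value) anchors."""
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    v = np.vander(x, 4, increasing=True)
    return [float(c) for c in np.linalg.solve(v, y)]


@dataclass
class GeneratorConfig:
    """Every knob of the synthetic cohort, explicit and serializable.

    Marker mean curves are ascending polynomial coefficients in ``ga_days``;
    ``pe_departure`` magnitudes are the marker-unit sizes of the level /
    trend / curvature components of the pre-diagnosis ramp (see
    :func:`pe_ramp`), jointly multiplied by ``departure_scale``.
    """

    n_subjects: int = 10_000
    seed: int = 0

    # baseline covariates
    maternal_age_mean: float = 29.33
    maternal_age_sd: float = 5.0
    height_mean: float = 166.6
    height_sd: float = 6.5
    category_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    boolean_prevalence: dict[str, float] = field(default_factory=dict)
    aspirin_rate: float = 0.011

    # outcome model
    outcome_coefficients: dict[str, float] = field(default_factory=dict)
    target_incidence: float = 0.044

    # event times (days)
    preterm_fraction_among_pe: float = 0.30
    dx_preterm_mean: float = 238.0
    dx_preterm_sd: float = 14.0
    dx_term_mean: float = 272.0
    dx_term_sd: float = 8.0
    diagnosis_to_delivery_shape: float = 2.0
    diagnosis_to_delivery_scale: float = 5.0
    delivery_mean: float = 281.0
    delivery_sd: float = 10.0

    # visit schedule
    first_visit_mean: float = 72.0
    first_visit_sd: float = 10.0
    first_visit_range: tuple[float, float] = (49.0, 112.0)
    gap_breaks: tuple[float, float] = (168.0, 238.0)
    gap_means: tuple[float, float, float] = (31.0, 17.0, 10.0)
    gap_sds: tuple[float, float, float] = (5.0, 3.0, 2.5)
    min_gap: float = 4.0
    case_extra_visit_rate: float = 1.5
    case_extra_window: float = 28.0

    # continuous markers
    marker_means: dict[str, list[float]] = field(default_factory=dict)
    marker_random_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    marker_noise_sd: dict[str, float] = field(default_factory=dict)
    pe_departure: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    pe_lead_time: float = 35.0
    departure_scale: float = 1.0
    bp_rounding: str = "none"  # {"none", "nearest5"}

    # categorical time-varying markers
    glucose_mean: float = 5.2
    glucose_sd: float = 0.8
    glucose_high_rate: dict[str, float] = field(
        default_factory=lambda: {"control": 0.033, "case": 0.053}
    )
    proteinuria_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (0.105, 0.013), "case": (0.260, 0.444)}
    )

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.pe_lead_time <= 0:
            raise ValueError("pe_lead_time must be > 0")
        probs = (
            [self.target_incidence, self.aspirin_rate]
            + list(self.boolean_prevalence.values())
            + list(self.glucose_high_rate.values())
            + [p for pair in self.proteinuria_rates.values() for p in pair]
            + [p for d in self.category_probs.values() for p in d.values()]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if self.bp_rounding not in ("none", "nearest5"):
            raise ValueError("bp_rounding must be 'none' or 'nearest5'")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = copy.deepcopy(d)
        cfg = cls(**d)
        # YAML round-trips tuples as lists; normalize back
        cfg.first_visit_range = tuple(cfg.first_visit_range)  # type: ignore
        cfg.gap_breaks = tuple(cfg.gap_breaks)  # type: ignore
        cfg.gap_means = tuple(cfg.gap_means)  # type: ignore
        cfg.gap_sds = tuple(cfg.gap_sds)  # type: ignore
        cfg.marker_random_effects = {
            k: tuple(v) for k, v in cfg.marker_random_effects.items()
        }
        cfg.pe_departure = {k: tuple(v) for k, v in cfg.pe_departure.items()}
        cfg.proteinuria_rates = {
            k: tuple(v) for k, v in cfg.proteinuria_rates.items()
        }
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(n_subjects: int = 10_000, seed: int = 0) -> GeneratorConfig:
    """Defaults calibrated to the study population's printed descriptives."""
    cfg = GeneratorConfig(n_subjects=n_subjects, seed=seed)
    cfg.category_probs = {
        "region_of_birth": {
            "Sweden": 0.742,
            "Nordic_other": 0.016,
            "Europe_other": 0.075,
            "Africa": 0.032,
            "North_America": 0.007,
            "South_America": 0.017,
            "Asia": 0.097,
            "Oceania": 0.001,
            "missing": 0.013,
        },
        "family_situation": {
            "single": 0.021,
            "with_partner": 0.918,
            "other": 0.054,
            "missing": 0.007,
        },
        "smoking_pre": {
            "none": 0.834,
            "lt10": 0.087,
            "ge10": 0.073,
            "missing": 0.006,
        },
        "smoking_early": {
            "none": 0.953,
            "lt10": 0.035,
            "ge10": 0.006,
            "missing": 0.006,
        },
        "infertility_duration": {"none": 0.836, "y1_2": 0.110, "gt2": 0.054},
        "infertility_treatment": {
            "none": 0.919,
            "ovarian_stimulation": 0.014,
            "ivf": 0.067,
        },
        "blood_group": {
            "O": 0.352,
            "A": 0.398,
            "AB": 0.051,
            "B": 0.122,
            "missing": 0.077,
        },
    }
    cfg.boolean_prevalence = {
        "prev_miscarriage": 0.176,
        "fam_hist_preeclampsia": 0.0025,
        "fam_hist_hypertension": 0.166,
        "cardiovascular_disease": 0.013,
        "endocrine_disease": 0.049,
        "preexisting_diabetes": 0.004,
        "thrombosis": 0.0,
        "sle": 0.001,
        "chronic_hypertension": 0.004,
        "ibd": 0.008,
        "chronic_kidney_disease": 0.004,
    }
    # log odds-ratios roughly consistent with the case/control contrasts of
    # the printed baseline table; intercept is solved at simulation time
    cfg.outcome_coefficients = {
        "maternal_age_c": 0.024,
        "height_cm_c": -0.012,
        "region_of_birth=Africa": 0.28,
        "region_of_birth=Asia": -0.42,
        "region_of_birth=Europe_other": -0.28,
        "family_situation=single": 0.20,
        "smoking_early=lt10": -0.25,
        "smoking_early=ge10": 0.25,
        "prev_miscarriage": 0.08,
        "infertility_duration=y1_2": 0.05,
        "infertility_duration=gt2": 0.37,
        "infertility_treatment=ovarian_stimulation": 0.20,
        "infertility_treatment=ivf": 0.20,
        "fam_hist_preeclampsia": 1.10,
        "fam_hist_hypertension": 0.40,
        "cardiovascular_disease": 0.30,
        "endocrine_disease": 0.27,
        "preexisting_diabetes": 1.70,
        "sle": 0.30,
        "chronic_hypertension": 1.35,
        "chronic_kidney_disease": 0.90,
        "blood_group=B": 0.09,
    }
    # mean curves through anchor points (days, marker units); cubic for the
    # markers with a second-trimester dip, linear ~1 cm/week for SF height
    cfg.marker_means = {
        "sbp": _cubic_through([(70, 118.0), (140, 113.0), (210, 116.0), (280, 122.0)]),
        "dbp": _cubic_through([(70, 70.0), (140, 66.0), (210, 69.0), (280, 75.0)]),
        "weight": _cubic_through([(70, 66.0), (140, 69.0), (210, 74.0), (280, 79.5)]),
        "hb": _cubic_through([(70, 131.0), (140, 121.0), (210, 120.0), (280, 126.0)]),
        "sf_height": [0.0, 1.0 / 7.0],
    }
    cfg.marker_random_effects = {
        "sbp": (8.0, 0.0),
        "dbp": (6.0, 0.0),
        "weight": (9.0, 0.0),
        "hb": (7.0, 0.0),
        "sf_height": (1.5, 0.0),
    }
    cfg.marker_noise_sd = {
        "sbp": 6.0,
        "dbp": 5.0,
        "weight": 1.0,
        "hb": 5.0,
        "sf_height": 1.5,
    }
    # (level, trend, curvature) magnitudes in marker units at the diagnosis
    # date; curvature dominant, sized so blood pressure reaches the
    # diagnostic range (>= 140/90) around diagnosis; SF-height departure
    # negative (fetal growth lag)
    cfg.pe_departure = {
        "sbp": (4.0, 3.0, 18.0),
        "dbp": (3.0, 2.0, 12.0),
        "weight": (0.5, 0.5, 3.0),
        "hb": (2.0, 1.0, 4.0),
        "sf_height": (-0.5, 0.0, -2.0),
    }
    return cfg


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class CohortBundle:
    """Generated cohort plus latent truth for recovery tests."""

    subjects: pd.DataFrame
    visits: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Pieces


def pe_ramp(
    config: GeneratorConfig,
    marker: str,
    ga_days: np.ndarray,
    ga_diagnosis_days: float,
) -> np.ndarray:
    """Trajectory departure of a preeclamptic woman at gestational ages ``ga_days``.

    With ``u = max(0, ga - (dx - lead)) / lead`` (0 at ramp onset, 1 at
    diagnosis, growing after), the departure is::

        level * (1 - exp(-2 u))  +  trend * u  +  curvature * u**2

    scaled by ``departure_scale``: a saturating level shift, a linear drift
    and a quadratic bend, separately controllable.
    """
    lvl, trd, crv = config.pe_departure[marker]
    s = config.departure_scale
    u = np.maximum(0.0, np.asarray(ga_days, dtype=float) - (ga_diagnosis_days - config.pe_lead_time))
    u /= config.pe_lead_time
    return s * (lvl * (1.0 - np.exp(-2.0 * u)) + trd * u + crv * u**2)


def simulate_visit_schedule(
    subject: dict | pd.Series, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Strictly increasing visit days for one woman, truncated at delivery.

    The first visit falls around week 10; inter-visit gaps shorten from
    roughly monthly to roughly weekly across the trimester breaks in
    ``config.gap_breaks``.  Preeclamptic women receive extra visits in the
    ``case_extra_window`` days before diagnosis.
    """
    delivery = float(subject["ga_delivery_days"])
    lo, hi = config.first_visit_range
    first = float(np.clip(rng.normal(config.first_visit_mean, config.first_visit_sd), lo, hi))
    first = min(first, delivery)
    times = [first]
    t = first
    while True:
        if t < config.gap_breaks[0]:
            phase = 0
        elif t < config.gap_breaks[1]:
            phase = 1
        else:
            phase = 2
        gap = max(config.min_gap, rng.normal(config.gap_means[phase], config.gap_sds[phase]))
        t = t + gap
        if t > delivery:
            break
        times.append(t)
    if subject.get("pe", False) and not pd.isna(subject.get("ga_diagnosis_days")):
        dx = float(subject["ga_diagnosis_days"])
        n_extra = rng.poisson(config.case_extra_visit_rate)
        for _ in range(n_extra):
            t_extra = dx - rng.uniform(0.0, config.case_extra_window)
            if first < t_extra <= delivery:
                times.append(t_extra)
    days = np.unique(np.round(np.asarray(times)).astype(int))
    days = days[(days >= 0) & (days <= delivery)]
    return days


def simulate_marker_series(
    subject: dict | pd.Series,
    schedule: np.ndarray,
    marker: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    random_effects: tuple[float, float] | None = None,
) -> np.ndarray:
    """Marker values at scheduled visits: mean curve + random effects + ramp + noise.

    Returns NaN before day 168 for symphysis-fundal height.  If
    ``random_effects`` is given it is used instead of drawing fresh ones
    (used by :func:`simulate_cohort` to keep the latent truth).
    """
    if marker not in config.marker_means:
        raise KeyError(f"unknown marker {marker!r}")
    ga = np.asarray(schedule, dtype=float)
    if random_effects is None:
        sd_b0, sd_b1 = config.marker_random_effects[marker]
        random_effects = (
            rng.normal(0.0, sd_b0) if sd_b0 > 0 else 0.0,
            rng.normal(0.0, sd_b1) if sd_b1 > 0 else 0.0,
        )
    b0, b1 = random_effects
    values = npoly.polyval(ga, np.asarray(config.marker_means[marker])) + b0 + b1 * (ga - 168.0)
    if subject.get("pe", False) and not pd.isna(subject.get("ga_diagnosis_days")):
        values = values + pe_ramp(config, marker, ga, float(subject["ga_diagnosis_days"]))
    noise_sd = config.marker_noise_sd[marker]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(ga))
    if marker in ("sbp", "dbp") and config.bp_rounding == "nearest5":
        values = 5.0 * np.round(values / 5.0)
    if marker == "sf_height":
        values = np.where(ga >= cm.SF_HEIGHT_MIN_DAYS, values, np.nan)
    return values


def simulate_categoricals(
    subject: dict | pd.Series,
    schedule: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Capillary glucose (mmol/L) and dipstick proteinuria category per visit.

    Group-specific probabilities of ever-high glucose (>= 9 mmol/L at any
    visit) and of the maximum dipstick category match the configured rates.
    For preeclamptic women, elevated dipstick readings are placed at or after
    ``diagnosis - lead_time``; controls get them at random visits.
    """
    n = len(schedule)
    is_case = bool(subject.get("pe", False)) and not pd.isna(subject.get("ga_diagnosis_days"))
    group = "case" if is_case else "control"

    glucose = np.minimum(rng.normal(config.glucose_mean, config.glucose_sd, size=n), 8.5)
    if n > 0 and rng.uniform() < config.glucose_high_rate[group]:
        glucose[rng.integers(n)] = rng.uniform(9.0, 11.0)

    proteinuria = np.zeros(n, dtype=int)
    p1, p2 = config.proteinuria_rates[group]
    u = rng.uniform()
    max_cat = 2 if u < p2 else (1 if u < p2 + p1 else 0)
    if n > 0 and max_cat > 0:
        if is_case:
            onset = float(subject["ga_diagnosis_days"]) - config.pe_lead_time
            eligible = np.flatnonzero(np.asarray(schedule, dtype=float) >= onset)
            if eligible.size == 0:
                eligible = np.array([n - 1])
        else:
            eligible = np.arange(n)
        n_elev = min(eligible.size, 1 + rng.binomial(2, 0.5))
        chosen = rng.choice(eligible, size=n_elev, replace=False)
        proteinuria[chosen] = max_cat if max_cat == 1 else rng.integers(1, 3, size=n_elev)
        proteinuria[chosen[0]] = max_cat  # guarantee the drawn maximum occurs
    return glucose, proteinuria


# ---------------------------------------------------------------------------
# Whole-cohort simulation


def _simulate_subjects(config: GeneratorConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    n = config.n_subjects
    df = pd.DataFrame(
        {"subject_id": pd.array([f"S{i:06d}" for i in range(n)], dtype="string")}
    )
    df["maternal_age"] = np.round(rng.normal(config.maternal_age_mean, config.maternal_age_sd, n), 1)
    df["height_cm"] = np.round(rng.normal(config.height_mean, config.height_sd, n), 1)
    for cat, probs in config.category_probs.items():
        levels = list(probs)
        p = np.asarray([probs[lv] for lv in levels], dtype=float)
        df[cat] = rng.choice(levels, size=n, p=p / p.sum())
    for col, prev in config.boolean_prevalence.items():
        df[col] = rng.uniform(size=n) < prev
    df["aspirin_use"] = rng.uniform(size=n) < config.aspirin_rate

    # outcome: logistic on encoded baseline covariates, intercept solved so
    # the marginal incidence hits the target
    df["pe"] = False
    df["ga_diagnosis_days"] = np.nan
    df["ga_delivery_days"] = 280
    eta = linear_predictor(df, config.outcome_coefficients)
    target = config.target_incidence
    if target <= 0.0:
        pe = np.zeros(n, dtype=bool)
    elif target >= 1.0:
        pe = np.ones(n, dtype=bool)
    else:
        alpha = brentq(lambda a: expit(a + eta).mean() - target, -30.0, 30.0)
        pe = rng.uniform(size=n) < expit(alpha + eta)
    df["pe"] = pe

    # event times
    n_pe = int(pe.sum())
    preterm = rng.uniform(size=n_pe) < config.preterm_fraction_among_pe
    dx = np.where(
        preterm,
        rng.normal(config.dx_preterm_mean, config.dx_preterm_sd, n_pe),
        rng.normal(config.dx_term_mean, config.dx_term_sd, n_pe),
    )
    dx = np.clip(np.round(dx), cm.MIN_DIAGNOSIS_DAYS + 15, 293).astype(int)
    gap = rng.gamma(config.diagnosis_to_delivery_shape, config.diagnosis_to_delivery_scale, n_pe)
    deliv_pe = np.minimum(np.round(dx + gap), 304).astype(int)
    deliv_ctrl = np.clip(
        np.round(rng.normal(config.delivery_mean, config.delivery_sd, n - n_pe)), 200, 301
    ).astype(int)
    delivery = np.empty(n, dtype=int)
    delivery[pe] = deliv_pe
    delivery[~pe] = deliv_ctrl
    ga_dx = np.full(n, np.nan)
    ga_dx[pe] = dx
    df["ga_diagnosis_days"] = ga_dx
    df["ga_delivery_days"] = delivery
    return df[cm.SUBJECT_COLUMNS], eta


def simulate_cohort(config: GeneratorConfig) -> CohortBundle:
    """Generate a full cohort bundle, deterministic for a given config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects, eta = _simulate_subjects(config, rng)

    markers = cm.CONTINUOUS_MARKERS
    re_draws = {
        m: np.column_stack(
            [
                rng.normal(0.0, config.marker_random_effects[m][0], config.n_subjects)
                if config.marker_random_effects[m][0] > 0
                else np.zeros(config.n_subjects),
                rng.normal(0.0, config.marker_random_effects[m][1], config.n_subjects)
                if config.marker_random_effects[m][1] > 0
                else np.zeros(config.n_subjects),
            ]
        )
        for m in markers
    }

    rows: dict[str, list] = {c: [] for c in cm.VISIT_COLUMNS}
    for i, subject in enumerate(subjects.to_dict("records")):
        schedule = simulate_visit_schedule(subject, config, rng)
        nv = len(schedule)
        rows["subject_id"].append(np.repeat(subject["subject_id"], nv))
        rows["ga_days"].append(schedule)
        series = {}
        for m in markers:
            series[m] = simulate_marker_series(
                subject, schedule, m, config, rng, random_effects=tuple(re_draws[m][i])
            )
        # keep the blood-pressure invariant sbp > dbp under independent noise
        series["dbp"] = np.minimum(series["dbp"], series["sbp"] - 5.0)
        glucose, prot = simulate_categoricals(subject, schedule, config, rng)
        for m in markers:
            rows[m].append(series[m])
        rows["glucose"].append(np.round(glucose, 1))
        rows["proteinuria"].append(prot.astype(float))
    visits = pd.DataFrame(
        {c: np.concatenate(rows[c]) if rows[c] else np.array([]) for c in cm.VISIT_COLUMNS}
    )
    visits["subject_id"] = visits["subject_id"].astype("string")
    for m in markers:
        visits[m] = np.round(visits[m], 1)

    truth = pd.DataFrame({"subject_id": subjects["subject_id"], "eta": eta})
    for m in markers:
        truth[f"{m}_b0"] = re_draws[m][:, 0]
        truth[f"{m}_b1"] = re_draws[m][:, 1]
    return CohortBundle(subjects=subjects, visits=visits, truth=truth, config=config)
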
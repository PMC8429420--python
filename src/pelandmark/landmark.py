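"""Landmark risk sets, outcome labels, design assembly and logistic models.

Stage 3 of the pipeline.  At each landmark week ``w`` the risk set contains
the women still predictable antenatally: not yet diagnosed with preeclampsia
and not yet delivered by the end of the completed week (``7 * (w + 1)``
days).  For each outcome a logistic regression is fitted by maximum
likelihood on the encoded baseline covariates, the 15 u-scores (5 markers x
level/trend/curvature), the glucose flag and two proteinuria dummies.

Outcomes (37 completed weeks = 259 days):

1. ``any_pe``       preeclampsia at any time in pregnancy
2. ``preterm_pe``   diagnosis and delivery before 37 weeks
3. ``term_pe``      diagnosis at any time with delivery at/after 37 weeks
4. ``dx_before_37`` diagnosis before 37 weeks (any delivery time)
5. ``dx_from_37``   diagnosis at/after 37 weeks

On detected separation or non-convergence the model is refitted with a weak
L2 penalty (1e-4 on standardized columns) and flagged in the diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from pelandmark.encoding import baseline_columns, encode_baseline
from pelandmark.features import landmark_end_day

#: 37 completed weeks in days
TERM_DAYS = 259

OUTCOMES = ["any_pe", "preterm_pe", "term_pe", "dx_before_37", "dx_from_37"]

RIDGE_PENALTY = 1e-4


class RiskModelError(RuntimeError):
    """Raised on unusable fitting input (too few cases, rank deficiency)."""


# ---------------------------------------------------------------------------
# Outcomes


def classify_outcomes(subjects: pd.DataFrame) -> pd.DataFrame:
    """Label the five preeclampsia outcomes for every subject.

    ``preterm_pe`` and ``term_pe`` partition the cases by delivery time;
    ``dx_before_37`` / ``dx_from_37`` partition them by diagnosis time.
    """
    pe = subjects["pe"].to_numpy(dtype=bool)
    dx = subjects["ga_diagnosis_days"].to_numpy(dtype=float)
    deliv = subjects["ga_delivery_days"].to_numpy(dtype=float)
    if (pe & np.isnan(dx)).any():
        bad = subjects.loc[pe & np.isnan(dx), "subject_id"].iloc[0]
        raise ValueError(f"subject {bad}: pe without ga_diagnosis_days")
    out = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"],
            "any_pe": pe,
            "preterm_pe": pe & (deliv < TERM_DAYS),
            "term_pe": pe & (deliv >= TERM_DAYS),
            "dx_before_37": pe & (dx < TERM_DAYS),
            "dx_from_37": pe & (dx >= TERM_DAYS),
        }
    )
    return out


def build_riskset(
    subjects: pd.DataFrame, landmark_week: int, exclude_aspirin: bool = False
) -> pd.Index:
    """Subjects still at risk (undiagnosed, undelivered) at a landmark week.

    Optionally excludes aspirin users for the sensitivity analysis.  Raises
    if the risk set is empty.
    """
    end = landmark_end_day(landmark_week)
    dx = subjects["ga_diagnosis_days"]
    keep = ~(dx.notna() & (dx < end)) & (subjects["ga_delivery_days"] >= end)
    if exclude_aspirin:
        keep &= ~subjects["aspirin_use"]
    ids = pd.Index(subjects.loc[keep, "subject_id"], name="subject_id")
    if len(ids) == 0:
        raise RiskModelError(f"empty risk set at landmark week {landmark_week}")
    return ids


# ---------------------------------------------------------------------------
# Design assembly


@dataclass
class LandmarkDataset:
    """Design matrix plus outcome labels for the at-risk women at one landmark."""

    landmark_week: int
    X: pd.DataFrame  # rows: at-risk subjects; columns: deterministic order
    labels: pd.DataFrame  # the five outcome indicator columns, same index
    encoding_metadata: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


def design_columns() -> list[str]:
    """Documented full design width: baseline + 15 u-scores + glucose + 2 proteinuria."""
    cols = list(baseline_columns())
    from pelandmark.cohort import CONTINUOUS_MARKERS
    from pelandmark.features import FEATURES

    for m in CONTINUOUS_MARKERS:
        cols += [f"u_{m}_{f}" for f in FEATURES]
    cols += ["glucose_high_ever", "proteinuria=1", "proteinuria=2"]
    return cols


def assemble_design(
    subjects: pd.DataFrame,
    riskset: pd.Index,
    uscores: pd.DataFrame,
    categorical: pd.DataFrame,
    landmark_week: int,
) -> LandmarkDataset:
    """Build the landmark design matrix in deterministic column order.

    ``uscores`` may omit markers whose scale was unavailable at this
    landmark; their columns are filled with 0 and flagged in
    ``encoding_metadata['zero_filled_markers']``.  Columns constant within
    the risk set (e.g. a covariate with prevalence 0) are dropped and
    recorded under ``'dropped_constant'``.  A risk-set member missing from
    the feature tables raises ``KeyError`` naming the subject.
    """
    subj = subjects.set_index("subject_id").loc[riskset].reset_index()
    X = encode_baseline(subj)

    for tbl, name in ((uscores, "u-scores"), (categorical, "categorical features")):
        missing = riskset.difference(tbl.index)
        if len(missing):
            raise KeyError(f"{name} missing for risk-set subject {missing[0]!r}")

    zero_filled = []
    full = design_columns()
    u_cols = [c for c in full if c.startswith("u_")]
    u = uscores.loc[riskset]
    for c in u_cols:
        if c in u.columns:
            X[c] = u[c].to_numpy(dtype=float)
        else:
            X[c] = 0.0
            zero_filled.append(c)
    cat = categorical.loc[riskset]
    X["glucose_high_ever"] = cat["glucose_high_ever"].to_numpy(dtype=float)
    X["proteinuria=1"] = (cat["proteinuria_max"].to_numpy() == 1).astype(float)
    X["proteinuria=2"] = (cat["proteinuria_max"].to_numpy() == 2).astype(float)
    assert list(X.columns) == full

    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    X = X.drop(columns=dropped)

    labels = classify_outcomes(subj).set_index("subject_id")
    labels = labels.loc[riskset]
    meta = {
        "landmark_week": landmark_week,
        "columns": list(X.columns),
        "dropped_constant": dropped,
        "zero_filled_markers": sorted(
            {
                m
                for c in zero_filled
                for m in ("sbp", "dbp", "weight", "hb", "sf_height")
                if c.startswith(f"u_{m}_")
            }
        ),
        "reference_levels": "largest printed category per covariate",
    }
    return LandmarkDataset(landmark_week, X, labels, meta)


# ---------------------------------------------------------------------------
# Risk model


@dataclass
class RiskModel:
    """Fitted logistic landmark model for one outcome."""

    outcome: str
    landmark_week: int
    intercept: float
    coefficients: pd.Series  # aligned to design columns
    regularization: str
    converged: bool
    log_likelihood: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "outcome": self.outcome,
                    "landmark_week": self.landmark_week,
                    "intercept": self.intercept,
                    "coefficients": {k: float(v) for k, v in self.coefficients.items()},
                    "regularization": self.regularization,
                    "converged": self.converged,
                    "log_likelihood": self.log_likelihood,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            outcome=d["outcome"],
            landmark_week=d["landmark_week"],
            intercept=d["intercept"],
            coefficients=pd.Series(d["coefficients"]),
            regularization=d["regularization"],
            converged=d["converged"],
            log_likelihood=d["log_likelihood"],
        )


def _ridge_logistic(X: np.ndarray, y: np.ndarray, penalty: float) -> np.ndarray:
    """Newton iterations for logistic regression with L2 penalty on
    standardized columns (intercept unpenalized)."""
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = np.column_stack([np.ones(len(X)), X / scale])
    lam = np.concatenate([[0.0], np.full(X.shape[1], penalty)])
    beta = np.zeros(Xs.shape[1])
    for _ in range(100):
        p = expit(Xs @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = Xs.T @ (y - p) - lam * beta
        hess = (Xs * w[:, None]).T @ Xs + np.diag(lam)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    # undo standardization
    out = np.empty_like(beta)
    out[1:] = beta[1:] / scale
    out[0] = beta[0]
    return out


def fit_risk_model(
    dataset: LandmarkDataset, outcome: str, min_cases: int = 10
) -> RiskModel:
    """Maximum-likelihood logistic regression for one outcome at one landmark.

    Requires at least ``min_cases`` cases in the dataset and a full-rank
    design; on separation or non-convergence, refits with a weak ridge
    penalty (1e-4 on standardized columns) and flags it.
    """
    if outcome not in dataset.labels.columns:
        raise KeyError(f"unknown outcome {outcome!r}")
    y = dataset.labels[outcome].to_numpy(dtype=float)
    n_cases = int(y.sum())
    if n_cases < min_cases:
        raise RiskModelError(
            f"{outcome} at week {dataset.landmark_week}: {n_cases} cases < {min_cases}"
        )
    X = dataset.X.to_numpy(dtype=float)
    Xc = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name the offending columns: constant or collinear with the rest
        bad = [c for c in dataset.X.columns if dataset.X[c].nunique() <= 1]
        if not bad:
            q, r = np.linalg.qr(Xc)
            bad = [
                dataset.X.columns[i - 1]
                for i in range(1, Xc.shape[1])
                if abs(r[i, i]) < 1e-8
            ]
        raise RiskModelError(
            f"design is rank-deficient (rank {rank} < {Xc.shape[1]}); "
            f"suspect columns: {bad}"
        )

    regularization = "none"
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            converged = bool(res.mle_retvals.get("converged", True))
            llf = float(res.llf)
            if not converged or not np.all(np.isfinite(params)):
                raise PerfectSeparationLike()
        except Exception:
            params = _ridge_logistic(X, y, RIDGE_PENALTY)
            regularization = f"ridge({RIDGE_PENALTY}) on standardized columns"
            converged = False
            p = expit(Xc @ params)
            llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    return RiskModel(
        outcome=outcome,
        landmark_week=dataset.landmark_week,
        intercept=float(params[0]),
        coefficients=pd.Series(params[1:], index=dataset.X.columns),
        regularization=regularization,
        converged=converged,
        log_likelihood=llf,
    )


class PerfectSeparationLike(Exception):
    """Internal marker: MLE unusable, fall back to ridge."""


def predict_risk(model: RiskModel, dataset: LandmarkDataset) -> pd.Series:
    """Predicted outcome probability per at-risk subject (inverse logit)."""
    if list(dataset.X.columns) != list(model.coefficients.index):
        raise ValueError(
            "design columns do not match model coefficients: "
            f"{list(dataset.X.columns)} vs {list(model.coefficients.index)}"
        )
    eta = model.intercept + dataset.X.to_numpy(dtype=float) @ model.coefficients.to_numpy()
    return pd.Series(expit(eta), index=dataset.X.index, name=model.outcome)
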
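"""Population mean trajectories of the continuous antenatal markers.

Stage 1 of the pipeline: for each marker, a linear mixed model is fitted to
all visits of the women *without* preeclampsia — a fixed-effect basis
expansion of gestational age (cubic B-spline by default, linear for
symphysis-fundal height) plus a random intercept per woman.  The fitted
fixed-effect curve is the non-preeclamptic population mean against which
every woman's departures are measured downstream.

Fitting uses statsmodels' ``MixedLM`` (REML); basis matrices come from
``scipy.interpolate.BSpline.design_matrix``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
import statsmodels.api as sm

from pelandmark.cohort import SF_HEIGHT_MIN_DAYS


class TrajectoryFitError(RuntimeError):
    """Raised on insufficient data or a non-converged mixed-model fit."""


@dataclass
class BasisSpec:
    """Fixed-effect basis for gestational age (days).

    ``kind='bspline'``: clamped cubic B-spline with the given boundary and
    interior knots (the basis spans constants, so no separate intercept).
    ``kind='linear'``: ``[1, ga]``.
    """

    kind: str = "bspline"
    degree: int = 3
    boundary: tuple[float, float] = (56.0, 300.0)
    interior_knots: tuple[float, ...] = (112.0, 168.0, 224.0)

    def design(self, ga_days: np.ndarray) -> np.ndarray:
        ga = np.atleast_1d(np.asarray(ga_days, dtype=float))
        if self.kind == "linear":
            return np.column_stack([np.ones_like(ga), ga])
        if self.kind != "bspline":
            raise ValueError(f"unknown basis kind {self.kind!r}")
        lo, hi = self.boundary
        t = np.concatenate(
            [
                np.repeat(lo, self.degree + 1),
                np.asarray(self.interior_knots, dtype=float),
                np.repeat(hi, self.degree + 1),
            ]
        )
        # clamp evaluation into the knot span; out-of-support values are the
        # caller's concern (predict_mean warns)
        gac = np.clip(ga, lo, hi - 1e-9)
        return BSpline.design_matrix(gac, t, self.degree).toarray()

    @property
    def n_columns(self) -> int:
        if self.kind == "linear":
            return 2
        return len(self.interior_knots) + self.degree + 1


def default_basis(marker: str) -> BasisSpec:
    """Cubic B-spline for the four whole-pregnancy markers, linear for SF height."""
    if marker == "sf_height":
        return BasisSpec(
            kind="linear",
            degree=1,
            boundary=(float(SF_HEIGHT_MIN_DAYS), 300.0),
            interior_knots=(),
        )
    return BasisSpec()


@dataclass
class TrajectoryModel:
    """Fitted population mean curve plus variance components for one marker."""

    marker: str
    basis: BasisSpec
    fixed_coefficients: np.ndarray
    random_intercept_sd: float
    residual_sd: float
    fit_n_subjects: int
    fit_n_obs: int
    ga_support: tuple[float, float]
    converged: bool = True

    # -- persistence --------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = {
            "marker": self.marker,
            "basis": asdict(self.basis),
            "fixed_coefficients": list(map(float, self.fixed_coefficients)),
            "random_intercept_sd": float(self.random_intercept_sd),
            "residual_sd": float(self.residual_sd),
            "fit_n_subjects": self.fit_n_subjects,
            "fit_n_obs": self.fit_n_obs,
            "ga_support": list(self.ga_support),
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrajectoryModel":
        d = json.loads(Path(path).read_text())
        b = d["basis"]
        basis = BasisSpec(
            kind=b["kind"],
            degree=b["degree"],
            boundary=tuple(b["boundary"]),
            interior_knots=tuple(b["interior_knots"]),
        )
        return cls(
            marker=d["marker"],
            basis=basis,
            fixed_coefficients=np.asarray(d["fixed_coefficients"]),
            random_intercept_sd=d["random_intercept_sd"],
            residual_sd=d["residual_sd"],
            fit_n_subjects=d["fit_n_subjects"],
            fit_n_obs=d["fit_n_obs"],
            ga_support=tuple(d["ga_support"]),
            converged=d["converged"],
        )


def fit_population_trajectory(
    subjects: pd.DataFrame,
    visits: pd.DataFrame,
    marker: str,
    basis: BasisSpec | None = None,
) -> TrajectoryModel:
    """Fit the non-preeclamptic population mean curve for one marker.

    ``subjects`` must contain only women with ``pe == False`` (passing any
    preeclamptic woman is a caller error, because the reference population is
    defined as unaffected).  All of each woman's non-missing measurements are
    used regardless of landmark.
    """
    if subjects["pe"].any():
        raise ValueError("training subjects must all have pe == False")
    if basis is None:
        basis = default_basis(marker)
    data = visits.loc[
        visits["subject_id"].isin(subjects["subject_id"]) & visits[marker].notna(),
        ["subject_id", "ga_days", marker],
    ]
    if marker == "sf_height" and (data["ga_days"] < SF_HEIGHT_MIN_DAYS).any():
        raise ValueError(
            f"sf_height observations before day {SF_HEIGHT_MIN_DAYS} are not valid"
        )
    n_subj = data["subject_id"].nunique()
    if len(data) < 2 or n_subj < 2:
        raise TrajectoryFitError(
            f"{marker}: need >= 2 observations from >= 2 subjects, "
            f"got {len(data)} obs / {n_subj} subjects"
        )
    ga = data["ga_days"].to_numpy(dtype=float)
    y = data[marker].to_numpy(dtype=float)
    X = basis.design(ga)
    support = (float(ga.min()), float(ga.max()))

    # degenerate zero-noise data (exactly on a basis function) makes the
    # mixed model singular; plain least squares is then exact
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_ols = y - X @ beta_ols
    if float(np.sqrt(np.mean(resid_ols**2))) < 1e-8:
        return TrajectoryModel(
            marker=marker,
            basis=basis,
            fixed_coefficients=beta_ols,
            random_intercept_sd=0.0,
            residual_sd=1e-12,
            fit_n_subjects=n_subj,
            fit_n_obs=len(data),
            ga_support=support,
        )

    model = sm.MixedLM(y, X, groups=data["subject_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
        if not result.converged:  # pragma: no cover - fallback path
            result = model.fit(reml=True, method="powell")
    if not result.converged:
        raise TrajectoryFitError(
            f"{marker}: mixed model did not converge; "
            f"optimizer history: {getattr(result, 'hist', None)}"
        )
    return TrajectoryModel(
        marker=marker,
        basis=basis,
        fixed_coefficients=np.asarray(result.fe_params),
        random_intercept_sd=float(np.sqrt(max(np.asarray(result.cov_re)[0, 0], 0.0))),
        residual_sd=float(np.sqrt(result.scale)),
        fit_n_subjects=n_subj,
        fit_n_obs=len(data),
        ga_support=support,
        converged=bool(result.converged),
    )


def predict_mean(model: TrajectoryModel, ga_days) -> np.ndarray | float:
    """Evaluate the fixed-effect population mean curve at ``ga_days``.

    Deterministic; emits a warning when asked to extrapolate beyond the
    gestational-age support of the training data.
    """
    ga = np.atleast_1d(np.asarray(ga_days, dtype=float))
    lo, hi = model.ga_support
    if ((ga < lo) | (ga > hi)).any():
        warnings.warn(
            f"{model.marker}: extrapolating outside fitted support [{lo}, {hi}]",
            stacklevel=2,
        )
    out = model.basis.design(ga) @ model.fixed_coefficients
    return out if np.ndim(ga_days) else float(out[0])


def residuals(model: TrajectoryModel, visits: pd.DataFrame) -> pd.DataFrame:
    """Observed minus population mean for one subject's visits, order preserved.

    Returns a DataFrame with columns ``ga_days`` and ``residual``; one row per
    non-missing measurement of the model's marker.
    """
    obs = visits.loc[visits[model.marker].notna(), ["ga_days", model.marker]]
    if len(obs) == 0:
        return pd.DataFrame({"ga_days": [], "residual": []})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = predict_mean(model, obs["ga_days"].to_numpy())
    return pd.DataFrame(
        {
            "ga_days": obs["ga_days"].to_numpy(dtype=float),
            "residual": obs[model.marker].to_numpy(dtype=float) - pred,
        }
    )
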
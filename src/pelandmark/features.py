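"""Per-woman trajectory features at a landmark: u-scores and categorical flags.

Stage 2 of the pipeline.  For each woman and marker, the residuals of her
measurements from the population mean curve — restricted to visits strictly
before the end of the landmark's completed week, ``ga_days < 7 * (week + 1)``
— are summarised by a least-squares fit on an orthogonal quadratic basis in
time: the intercept is the *level*, the linear coefficient the *trend* (per
week) and the quadratic coefficient the *curvature* (per week squared) of her
departure.  Raw coefficients are standardized against their dispersion among
the non-preeclamptic women at risk at the same landmark, giving u-scores
(z-score-like standardized departures).

Women with too few observations are shrunk toward the population mean rather
than dropped: with two observations the curvature is 0 and level/trend come
from the exact line, with one observation the residual itself is the level,
with none all three coefficients are 0.  Every at-risk woman therefore
receives a feature vector, whatever her visit history.

The two categorical time-varying markers are reduced to "capillary glucose
ever >= 9 mmol/L" and the maximum dipstick proteinuria category (0 if never
measured) within the same landmark window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pelandmark.trajectory import TrajectoryModel

FEATURES = ("level", "trend", "curvature")

#: minimum observation counts for a raw coefficient to be estimated (rather
#: than shrunk to 0) and to contribute to scale estimation
MIN_OBS = {"level": 1, "trend": 2, "curvature": 3}

_DEGENERATE_TOL = 1e-10
GLUCOSE_HIGH_THRESHOLD = 9.0


class UScoreScaleError(RuntimeError):
    """Raised when a u-score scale cannot be reliably estimated."""


def landmark_end_day(landmark_week: int) -> int:
    """First gestational day *not* available at the landmark (7 * (w + 1))."""
    return 7 * (landmark_week + 1)


# ---------------------------------------------------------------------------
# Raw coefficients


def raw_trajectory_coefficients(
    ga_days: np.ndarray, residuals: np.ndarray
) -> tuple[float, float, float, int]:
    """Level / trend / curvature of one woman's residual trajectory.

    ``ga_days``/``residuals`` must already be truncated to the landmark
    window.  Time is centered at the midpoint of the woman's observed
    gestational ages and expressed in weeks, then the quadratic basis is
    orthogonalized (Gram–Schmidt on her own time points) so the three
    coefficients are uncorrelated projections.
    """
    t = np.asarray(ga_days, dtype=float)
    r = np.asarray(residuals, dtype=float)
    n = len(t)
    if n == 0:
        return 0.0, 0.0, 0.0, 0
    if n == 1:
        return float(r[0]), 0.0, 0.0, 1
    t = (t - (t.min() + t.max()) / 2.0) / 7.0
    level = float(r.mean())
    p1 = t - t.mean()
    s11 = float(p1 @ p1)
    if s11 < _DEGENERATE_TOL:  # all observations at one time point
        return level, 0.0, 0.0, n
    trend = float(r @ p1) / s11
    if n == 2:
        return level, trend, 0.0, 2
    alpha = float((t**2) @ p1) / s11
    beta = float(np.mean(t**2))
    p2 = t**2 - alpha * p1 - beta
    s22 = float(p2 @ p2)
    if s22 < _DEGENERATE_TOL:  # only two distinct time points
        return level, trend, 0.0, n
    curvature = float(r @ p2) / s22
    return level, trend, curvature, n


def compute_raw_features(
    visits: pd.DataFrame,
    models: dict[str, TrajectoryModel],
    landmark_week: int,
    subject_ids: pd.Index | pd.Series | None = None,
) -> pd.DataFrame:
    """Raw level/trend/curvature per woman and marker at one landmark.

    Vectorized over the whole cohort via grouped moment sums; identical to
    calling :func:`raw_trajectory_coefficients` per woman.  Returns a frame
    indexed by ``subject_id`` with columns ``{marker}_{feature}`` and
    ``{marker}_n_obs``; rows are all subjects in ``subject_ids`` (default:
    every subject appearing in ``visits``).
    """
    if subject_ids is None:
        subject_ids = visits["subject_id"].unique()
    index = pd.Index(subject_ids, name="subject_id")
    pos = pd.Series(np.arange(len(index)), index=index)
    out = pd.DataFrame(index=index)
    end = landmark_end_day(landmark_week)
    win = visits[visits["ga_days"] < end]

    for marker, model in models.items():
        obs = win[win[marker].notna() & win["subject_id"].isin(index)]
        g = pos.loc[obs["subject_id"]].to_numpy()
        ga = obs["ga_days"].to_numpy(dtype=float)
        resid = obs[marker].to_numpy(dtype=float) - model.basis.design(ga) @ model.fixed_coefficients
        k = len(index)

        n = np.bincount(g, minlength=k).astype(float)
        tmin = np.full(k, np.inf)
        tmax = np.full(k, -np.inf)
        np.minimum.at(tmin, g, ga)
        np.maximum.at(tmax, g, ga)
        has_obs = n > 0
        center = np.zeros(k)
        center[has_obs] = (tmin[has_obs] + tmax[has_obs]) / 2.0
        t = (ga - center[g]) / 7.0

        def gsum(x):
            return np.bincount(g, weights=x, minlength=k)

        s1, s2, s3, s4 = gsum(t), gsum(t**2), gsum(t**3), gsum(t**4)
        r0, r1, r2 = gsum(resid), gsum(resid * t), gsum(resid * t**2)

        with np.errstate(divide="ignore", invalid="ignore"):
            level = np.where(n > 0, r0 / np.where(n > 0, n, 1), 0.0)
            tbar = s1 / np.where(n > 0, n, 1)
            s11 = s2 - s1 * tbar
            trend_num = r1 - tbar * r0
            trend = np.where((n >= 2) & (s11 >= _DEGENERATE_TOL), trend_num / np.where(s11 > 0, s11, 1), 0.0)
            alpha = (s3 - tbar * s2) / np.where(s11 > 0, s11, 1)
            beta = s2 / np.where(n > 0, n, 1)
            s22 = s4 - 2 * alpha * (s3 - tbar * s2) - 2 * beta * s2 + alpha**2 * s11 + beta**2 * n
            curv_num = r2 - alpha * trend_num - beta * r0
            curv = np.where(
                (n >= 3) & (s11 >= _DEGENERATE_TOL) & (s22 >= _DEGENERATE_TOL),
                curv_num / np.where(s22 > 0, s22, 1),
                0.0,
            )
        out[f"{marker}_level"] = level
        out[f"{marker}_trend"] = trend
        out[f"{marker}_curvature"] = curv
        out[f"{marker}_n_obs"] = n.astype(int)
    return out


# ---------------------------------------------------------------------------
# Scales / u-scores


@dataclass
class UScoreScale:
    """Centers and dispersions of raw coefficients among non-PE at-risk women."""

    marker: str
    landmark_week: int
    center: dict[str, float]
    sd: dict[str, float]
    n_contributing: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "landmark_week": self.landmark_week,
            "center": self.center,
            "sd": self.sd,
            "n_contributing": self.n_contributing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UScoreScale":
        return cls(**d)


def fit_uscore_scale(
    raw: pd.DataFrame,
    marker: str,
    landmark_week: int,
    min_contributors: int = 30,
) -> UScoreScale:
    """Estimate the u-score scale for one marker at one landmark.

    ``raw`` must be the output of :func:`compute_raw_features` restricted to
    the non-preeclamptic women at risk at the landmark.  Only women with
    enough observations contribute to each feature's dispersion (>= 1 for
    level, >= 2 for trend, >= 3 for curvature).  Raises
    :class:`UScoreScaleError` when a feature has fewer than
    ``min_contributors`` contributing women or near-zero dispersion.
    """
    center: dict[str, float] = {}
    sd: dict[str, float] = {}
    n_contrib: dict[str, int] = {}
    n_obs = raw[f"{marker}_n_obs"]
    for feat in FEATURES:
        vals = raw.loc[n_obs >= MIN_OBS[feat], f"{marker}_{feat}"]
        n_contrib[feat] = len(vals)
        if len(vals) < min_contributors:
            raise UScoreScaleError(
                f"{marker} {feat} at week {landmark_week}: only {len(vals)} "
                f"contributing women (< {min_contributors})"
            )
        s = float(vals.std(ddof=1))
        if s < 1e-8:
            raise UScoreScaleError(
                f"{marker} {feat} at week {landmark_week}: dispersion {s} below floor"
            )
        center[feat] = float(vals.mean())
        sd[feat] = s
    return UScoreScale(marker, landmark_week, center, sd, n_contrib)


def compute_uscores(
    raw: pd.DataFrame, scales: dict[str, UScoreScale]
) -> pd.DataFrame:
    """Standardize raw coefficients: ``u = (raw - center) / sd`` per feature.

    ``raw`` is the frame from :func:`compute_raw_features` (any set of
    subjects); a scale must exist for every marker column present in ``raw``
    that is requested via ``scales``.  Returns columns ``u_{marker}_{feature}``.
    """
    out = pd.DataFrame(index=raw.index)
    for marker, scale in scales.items():
        if f"{marker}_level" not in raw.columns:
            raise KeyError(f"raw features missing marker {marker!r}")
        for feat in FEATURES:
            out[f"u_{marker}_{feat}"] = (
                raw[f"{marker}_{feat}"] - scale.center[feat]
            ) / scale.sd[feat]
    return out


def uscores_for_subject(
    visits_of_subject: pd.DataFrame,
    models: dict[str, TrajectoryModel],
    scales: dict[str, UScoreScale],
    landmark_week: int,
) -> dict[str, float]:
    """u-scores for a single woman at a landmark (convenience wrapper).

    Markers without a scale (e.g. symphysis-fundal height before enough
    follow-up has accrued) are omitted; a missing scale for a requested
    marker in ``models`` but absent from ``scales`` raises ``KeyError`` only
    when accessed downstream, mirroring the pipeline's explicit flagging.
    """
    end = landmark_end_day(landmark_week)
    win = visits_of_subject[visits_of_subject["ga_days"] < end]
    result: dict[str, float] = {}
    for marker, scale in scales.items():
        model = models[marker]
        obs = win[win[marker].notna()]
        ga = obs["ga_days"].to_numpy(dtype=float)
        resid = (
            obs[marker].to_numpy(dtype=float)
            - model.basis.design(ga) @ model.fixed_coefficients
            if len(obs)
            else np.array([])
        )
        lvl, trd, crv, n = raw_trajectory_coefficients(ga, resid)
        for feat, val in zip(FEATURES, (lvl, trd, crv)):
            result[f"u_{marker}_{feat}"] = (val - scale.center[feat]) / scale.sd[feat]
        result[f"{marker}_n_obs"] = n
    return result


# ---------------------------------------------------------------------------
# Categorical time-varying features


def compute_categorical_features(
    visits: pd.DataFrame, landmark_week: int
) -> pd.DataFrame:
    """Glucose-ever-high flag and maximum dipstick category per woman.

    Uses only visits with ``ga_days < 7 * (week + 1)``.  ``glucose_high_ever``
    is true if any capillary glucose reading was >= 9 mmol/L (boundary
    inclusive); ``proteinuria_max`` is the maximum dipstick category observed,
    0 if proteinuria was never measured in the window.
    """
    end = landmark_end_day(landmark_week)
    win = visits[visits["ga_days"] < end]
    grouped = win.groupby("subject_id", observed=True)
    glucose = grouped["glucose"].apply(
        lambda g: bool((g.dropna() >= GLUCOSE_HIGH_THRESHOLD).any())
    )
    prot = grouped["proteinuria"].max().fillna(0).astype(int)
    out = pd.DataFrame({"glucose_high_ever": glucose, "proteinuria_max": prot})
    # subjects with no in-window visits at all
    all_ids = pd.Index(visits["subject_id"].unique(), name="subject_id")
    out = out.reindex(all_ids)
    out["glucose_high_ever"] = out["glucose_high_ever"].eq(True)
    out["proteinuria_max"] = out["proteinuria_max"].fillna(0).astype(int)
    out.index.name = "subject_id"
    return out
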
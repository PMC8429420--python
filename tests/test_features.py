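"""u-score raw coefficients, scales, standardization and categorical features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pelandmark import features as ft
from pelandmark import synth
from pelandmark import trajectory as tj


def oracle_coefficients(ga, resid):
    """Independent normal-equations fit on the explicitly built orthogonal basis."""
    t = (np.asarray(ga, float) - (min(ga) + max(ga)) / 2.0) / 7.0
    r = np.asarray(resid, float)
    p0 = np.ones_like(t)
    p1 = t - t.mean()
    alpha = (t**2 @ p1) / (p1 @ p1)
    beta = np.mean(t**2)
    p2 = t**2 - alpha * p1 - beta
    B = np.column_stack([p0, p1, p2])
    c, *_ = np.linalg.lstsq(B, r, rcond=None)
    return c


def test_worked_example_matches_oracle():
    ga = [140.0, 168.0, 196.0]
    resid = [1.0, 2.0, 4.0]
    lvl, trd, crv, n = ft.raw_trajectory_coefficients(ga, resid)
    c = oracle_coefficients(ga, resid)
    np.testing.assert_allclose([lvl, trd, crv], c, atol=1e-12)
    assert crv > 0  # residuals accelerate upward
    assert n == 3


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_raw_coefficients_equal_least_squares_oracle(data):
    n = data.draw(st.integers(min_value=3, max_value=12))
    ga = data.draw(
        st.lists(
            st.integers(min_value=50, max_value=280),
            min_size=n, max_size=n, unique=True,
        )
    )
    resid = data.draw(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    ga = np.sort(np.array(ga, dtype=float))
    got = ft.raw_trajectory_coefficients(ga, resid)[:3]
    np.testing.assert_allclose(got, oracle_coefficients(ga, resid), atol=1e-10)


@pytest.mark.parametrize(
    "ga, resid, expected",
    [
        ([], [], (0.0, 0.0, 0.0, 0)),  # no observations: population mean
        ([100.0], [7.5], (7.5, 0.0, 0.0, 1)),  # single residual is the level
        ([100.0, 114.0], [1.0, 3.0], (2.0, 1.0, 0.0, 2)),  # exact line, slope/week
    ],
)
def test_degenerate_observation_rules(ga, resid, expected):
    assert ft.raw_trajectory_coefficients(ga, resid) == pytest.approx(expected)


def test_zero_and_linear_residuals():
    ga = np.array([80.0, 120.0, 170.0, 230.0])
    lvl, trd, crv, _ = ft.raw_trajectory_coefficients(ga, np.zeros(4))
    assert (lvl, trd, crv) == (0.0, 0.0, 0.0)
    line = 0.5 * (ga - 150.0) / 7.0
    lvl, trd, crv, _ = ft.raw_trajectory_coefficients(ga, line)
    assert crv == pytest.approx(0.0, abs=1e-12)
    assert trd == pytest.approx(0.5 / 7.0 * 7.0, abs=1e-12)  # 0.5 per week


def test_batch_path_equals_scalar_path(small_bundle, small_models):
    week = 34
    raw = ft.compute_raw_features(small_bundle.visits, small_models, week)
    end = ft.landmark_end_day(week)
    rng = np.random.default_rng(0)
    ids = rng.choice(raw.index.to_numpy(), size=40, replace=False)
    for sid in ids:
        grp = small_bundle.visits[
            (small_bundle.visits["subject_id"] == sid)
            & (small_bundle.visits["ga_days"] < end)
        ]
        for marker in ["sbp", "weight", "sf_height"]:
            obs = grp[grp[marker].notna()]
            r = tj.residuals(small_models[marker], obs)
            lvl, trd, crv, n = ft.raw_trajectory_coefficients(
                r["ga_days"].to_numpy(), r["residual"].to_numpy()
            )
            np.testing.assert_allclose(
                [
                    raw.loc[sid, f"{marker}_level"],
                    raw.loc[sid, f"{marker}_trend"],
                    raw.loc[sid, f"{marker}_curvature"],
                ],
                [lvl, trd, crv],
                atol=1e-9,
            )
            assert raw.loc[sid, f"{marker}_n_obs"] == n


def test_scale_standardization_identity(small_bundle, small_models):
    """Applying a scale to its fitting sample gives mean ~0, SD ~1 per feature."""
    week = 32
    nonpe = small_bundle.subjects.loc[~small_bundle.subjects["pe"], "subject_id"]
    raw = ft.compute_raw_features(
        small_bundle.visits, small_models, week, subject_ids=nonpe
    )
    scale = ft.fit_uscore_scale(raw, "sbp", week)
    u = ft.compute_uscores(raw, {"sbp": scale})
    for feat in ft.FEATURES:
        col = u[f"u_sbp_{feat}"][raw["sbp_n_obs"] >= ft.MIN_OBS[feat]]
        assert abs(col.mean()) < 1e-10
        assert abs(col.std(ddof=1) - 1.0) < 1e-10


def test_scale_errors():
    idx = pd.Index([f"s{i}" for i in range(40)], name="subject_id")
    raw = pd.DataFrame(
        {
            "sbp_level": np.linspace(-1, 1, 40),
            "sbp_trend": np.linspace(-1, 1, 40),
            "sbp_curvature": np.linspace(-1, 1, 40),
            "sbp_n_obs": 5,
        },
        index=idx,
    )
    with pytest.raises(ft.UScoreScaleError, match="contributing"):
        ft.fit_uscore_scale(raw.iloc[:20], "sbp", 28)
    const = raw.copy()
    const["sbp_curvature"] = 0.3  # identical coefficients: dispersion floor
    with pytest.raises(ft.UScoreScaleError, match="floor"):
        ft.fit_uscore_scale(const, "sbp", 28)


def test_uscores_center_and_shrinkage():
    idx = pd.Index(["a"], name="subject_id")
    raw = pd.DataFrame(
        {"sbp_level": [4.0], "sbp_trend": [0.0], "sbp_curvature": [0.0], "sbp_n_obs": [1]},
        index=idx,
    )
    scale = ft.UScoreScale(
        "sbp", 28, {"level": 1.0, "trend": 0.5, "curvature": -0.2},
        {"level": 2.0, "trend": 1.0, "curvature": 0.1}, {"level": 40, "trend": 40, "curvature": 40},
    )
    u = ft.compute_uscores(raw, {"sbp": scale})
    assert u.loc["a", "u_sbp_level"] == pytest.approx(1.5)
    # single-visit woman: raw trend/curvature are 0, still standardized
    assert u.loc["a", "u_sbp_trend"] == pytest.approx(-0.5)
    assert u.loc["a", "u_sbp_curvature"] == pytest.approx(2.0)
    with pytest.raises(KeyError):
        ft.compute_uscores(raw.drop(columns=["sbp_level"]), {"sbp": scale})


def test_case_curvature_uscores_exceed_controls(small_bundle, small_models):
    """Mean curvature u-score among cases is above the control mean (sbp)."""
    week = 34
    from pelandmark import landmark as lm

    riskset = lm.build_riskset(small_bundle.subjects, week)
    raw = ft.compute_raw_features(
        small_bundle.visits, small_models, week, subject_ids=riskset
    )
    pe = small_bundle.subjects.set_index("subject_id")["pe"]
    scale = ft.fit_uscore_scale(raw[~pe.loc[raw.index]], "sbp", week)
    u = ft.compute_uscores(raw, {"sbp": scale})["u_sbp_curvature"]
    assert u[pe.loc[u.index]].mean() > u[~pe.loc[u.index]].mean()


def test_glucose_boundary_inclusive_and_proteinuria_defaults(tiny):
    _, visits = tiny
    visits = visits.copy()
    visits.loc[1, "glucose"] = 9.0  # boundary reading counts as high
    feats = ft.compute_categorical_features(visits, 36)
    assert bool(feats.loc["A", "glucose_high_ever"])
    # proteinuria never measured for A after dropping its one reading
    visits.loc[0, "proteinuria"] = np.nan
    feats = ft.compute_categorical_features(visits, 36)
    assert feats.loc["A", "proteinuria_max"] == 0


def test_landmark_truncation_of_categoricals(tiny):
    _, visits = tiny
    # B's dipstick 2 is recorded at day 200 >= end of week 24 (175): excluded
    feats24 = ft.compute_categorical_features(visits, 24)
    assert feats24.loc["B", "proteinuria_max"] == 0
    assert not bool(feats24.loc["B", "glucose_high_ever"])
    feats36 = ft.compute_categorical_features(visits, 36)
    assert feats36.loc["B", "proteinuria_max"] == 2
    assert bool(feats36.loc["B", "glucose_high_ever"])


def test_no_information_leakage_past_landmark(small_bundle, small_models):
    """Perturbing all post-landmark measurements leaves features unchanged."""
    week = 28
    end = ft.landmark_end_day(week)
    visits = small_bundle.visits.copy()
    late = visits["ga_days"] >= end
    for col in ["sbp", "dbp", "weight", "hb", "sf_height", "glucose"]:
        visits.loc[late, col] = visits.loc[late, col] + 500.0
    visits.loc[late, "proteinuria"] = 2.0
    raw0 = ft.compute_raw_features(small_bundle.visits, small_models, week)
    raw1 = ft.compute_raw_features(visits, small_models, week)
    pd.testing.assert_frame_equal(raw0, raw1)
    pd.testing.assert_frame_equal(
        ft.compute_categorical_features(small_bundle.visits, week),
        ft.compute_categorical_features(visits, week),
    )
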
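"""Outcome labels, risk sets, design assembly and logistic risk models."""

import numpy as np
import pandas as pd
import pytest

from pelandmark import features as ft
from pelandmark import landmark as lm
from pelandmark import synth
from pelandmark.encoding import encode_baseline


def _subject(sid, pe=False, dx=np.nan, delivery=280, aspirin=False):
    from tests.conftest import tiny_cohort

    row = tiny_cohort()[0].iloc[0].copy()
    row["subject_id"] = sid
    row["pe"] = pe
    row["ga_diagnosis_days"] = dx
    row["ga_delivery_days"] = delivery
    row["aspirin_use"] = aspirin
    return row


def _subjects(rows):
    return pd.DataFrame(rows).reset_index(drop=True)


def test_outcome_definitions_at_37_weeks():
    subjects = _subjects(
        [
            _subject("early", pe=True, dx=245.0, delivery=252),
            _subject("late_dx_early", pe=True, dx=250.0, delivery=262),
            _subject("term", pe=True, dx=262.0, delivery=270),
            _subject("none"),
        ]
    )
    labels = lm.classify_outcomes(subjects).set_index("subject_id")
    assert labels.loc["early"].tolist() == [True, True, False, True, False]
    # diagnosis before 37 weeks but delivery at term: term PE and early diagnosis
    assert labels.loc["late_dx_early"].tolist() == [True, False, True, True, False]
    assert labels.loc["term"].tolist() == [True, False, True, False, True]
    assert not labels.loc["none"].any()


def test_pe_without_diagnosis_ga_rejected():
    subjects = _subjects([_subject("x", pe=True, dx=np.nan)])
    with pytest.raises(ValueError, match="without ga_diagnosis_days"):
        lm.classify_outcomes(subjects)


def test_riskset_excludes_diagnosed_and_delivered():
    subjects = _subjects(
        [
            _subject("dx_early", pe=True, dx=160.0, delivery=200),
            _subject("dx_late", pe=True, dx=250.0, delivery=260),
            _subject("delivered", delivery=170),
            _subject("ok"),
        ]
    )
    rs = lm.build_riskset(subjects, 24)
    assert set(rs) == {"dx_late", "ok"}  # 160 < 175 and delivery 170 < 175
    rs36 = lm.build_riskset(subjects, 36)
    assert set(rs36) == {"ok"}
    assert set(rs36) <= set(rs)  # risk sets shrink with landmark week


def test_riskset_aspirin_exclusion(small_bundle):
    subjects = small_bundle.subjects
    with_asp = lm.build_riskset(subjects, 24, exclude_aspirin=False)
    without = lm.build_riskset(subjects, 24, exclude_aspirin=True)
    n_asp = int(
        subjects.set_index("subject_id").loc[with_asp, "aspirin_use"].sum()
    )
    assert len(with_asp) - len(without) == n_asp
    assert not subjects.set_index("subject_id").loc[without, "aspirin_use"].any()


def test_riskset_empty_is_error():
    subjects = _subjects([_subject("only", delivery=160)])
    with pytest.raises(lm.RiskModelError, match="empty risk set"):
        lm.build_riskset(subjects, 24)


def _toy_dataset(n=400, seed=0, n_features=3, signal=1.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"x{i}" for i in range(n_features)],
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )
    eta = signal * X["x0"].to_numpy()
    y = rng.uniform(size=n) < 1 / (1 + np.exp(-eta))
    labels = pd.DataFrame({"any_pe": y}, index=X.index)
    return lm.LandmarkDataset(28, X, labels, {"columns": list(X.columns)})


def test_design_schema_and_shuffle_invariance(small_bundle, small_models):
    week = 34
    riskset = lm.build_riskset(small_bundle.subjects, week)
    raw = ft.compute_raw_features(
        small_bundle.visits, small_models, week, subject_ids=riskset
    )
    pe = small_bundle.subjects.set_index("subject_id")["pe"]
    scales = {
        m: ft.fit_uscore_scale(raw[~pe.loc[raw.index]], m, week)
        for m in ["sbp", "dbp", "weight", "hb", "sf_height"]
    }
    uscores = ft.compute_uscores(raw, scales)
    cats = ft.compute_categorical_features(small_bundle.visits, week)
    ds = lm.assemble_design(small_bundle.subjects, riskset, uscores, cats, week)
    # full documented width minus columns constant in this cohort
    assert set(ds.X.columns) | set(ds.encoding_metadata["dropped_constant"]) == set(
        lm.design_columns()
    )
    assert len(lm.design_columns()) == 56
    # row order of the inputs does not matter
    shuffled = small_bundle.subjects.sample(frac=1.0, random_state=1)
    ds2 = lm.assemble_design(shuffled, riskset, uscores, cats, week)
    pd.testing.assert_frame_equal(ds.X, ds2.X)
    # missing feature rows are reported by subject
    with pytest.raises(KeyError, match="missing"):
        lm.assemble_design(
            small_bundle.subjects, riskset, uscores.iloc[10:], cats, week
        )


def test_logistic_recovers_generating_coefficients():
    """Strong baseline coefficients are recovered within 2 SEs at n=8,000."""
    cfg = synth.default_config(n_subjects=8000, seed=5)
    bundle = synth.simulate_cohort(cfg)
    X = encode_baseline(bundle.subjects)
    labels = pd.DataFrame(
        {"any_pe": bundle.subjects["pe"].to_numpy()}, index=X.index
    )
    X = X.loc[:, X.nunique() > 1]
    ds = lm.LandmarkDataset(24, X, labels, {})
    model = lm.fit_risk_model(ds, "any_pe")
    import statsmodels.api as sm

    fit = sm.Logit(
        labels["any_pe"].to_numpy(dtype=float),
        np.column_stack([np.ones(len(X)), X.to_numpy()]),
    ).fit(disp=0)
    se = np.asarray(fit.bse)[1:]
    for i, col in enumerate(["maternal_age_c", "fam_hist_hypertension", "preexisting_diabetes"]):
        j = list(X.columns).index(col)
        true = cfg.outcome_coefficients.get(col, 0.0)
        assert abs(model.coefficients[col] - true) < 2 * se[j], col


def test_too_few_cases_rejected():
    ds = _toy_dataset(n=60)
    ds.labels["any_pe"] = False
    ds.labels.iloc[:3, 0] = True
    with pytest.raises(lm.RiskModelError, match="cases"):
        lm.fit_risk_model(ds, "any_pe")


def test_constant_column_is_rank_deficiency_error():
    ds = _toy_dataset()
    ds.X["const"] = 1.0
    with pytest.raises(lm.RiskModelError, match="rank-deficient.*const"):
        lm.fit_risk_model(ds, "any_pe")


def test_separation_falls_back_to_ridge():
    ds = _toy_dataset(n=200, signal=0.0)
    ds.X["sep"] = ds.labels["any_pe"].astype(float)  # perfect separator
    model = lm.fit_risk_model(ds, "any_pe")
    assert "ridge" in model.regularization
    assert not model.converged
    probs = lm.predict_risk(model, ds)
    assert ((probs > 0) & (probs < 1)).all()


def test_predict_risk_consistency_and_monotonicity():
    ds = _toy_dataset(n=500, seed=3)
    model = lm.fit_risk_model(ds, "any_pe")
    probs = lm.predict_risk(model, ds)
    # training predictions reproduce the fitted values
    import statsmodels.api as sm

    fit = sm.Logit(
        ds.labels["any_pe"].to_numpy(dtype=float),
        np.column_stack([np.ones(len(ds.X)), ds.X.to_numpy()]),
    ).fit(disp=0)
    np.testing.assert_allclose(probs.to_numpy(), fit.predict(), atol=1e-10)
    # increasing a positively weighted feature raises the probability
    col = model.coefficients.abs().idxmax()
    sign = np.sign(model.coefficients[col])
    bumped = ds.X.copy()
    bumped[col] = bumped[col] + sign
    ds2 = lm.LandmarkDataset(ds.landmark_week, bumped, ds.labels, ds.encoding_metadata)
    assert (lm.predict_risk(model, ds2) > probs).all()
    # schema mismatch is an error
    ds3 = lm.LandmarkDataset(28, ds.X.iloc[:, :-1], ds.labels, {})
    with pytest.raises(ValueError, match="columns"):
        lm.predict_risk(model, ds3)


def test_all_zero_model_predicts_half():
    ds = _toy_dataset(n=50)
    model = lm.RiskModel(
        outcome="any_pe", landmark_week=28, intercept=0.0,
        coefficients=pd.Series(0.0, index=ds.X.columns),
        regularization="none", converged=True, log_likelihood=0.0,
    )
    assert (lm.predict_risk(model, ds) == 0.5).all()


def test_wald_test_calibrated_under_null():
    """Per-coefficient Wald rejection rate is ~5% when no predictor matters."""
    import statsmodels.api as sm

    rng = np.random.default_rng(7)
    rejections = 0
    total = 0
    for _ in range(200):
        X = rng.normal(size=(300, 3))
        y = rng.uniform(size=300) < 0.3
        fit = sm.Logit(y.astype(float), np.column_stack([np.ones(300), X])).fit(disp=0)
        z = np.asarray(fit.params / fit.bse)[1:]
        rejections += int((np.abs(z) > 1.96).sum())
        total += 3
    rate = rejections / total
    assert 0.02 < rate < 0.09
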
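"""ROC analysis for the landmark models.

Empirical ROC curves with tied scores grouped into single steps, the
Mann–Whitney AUC (ties counted 1/2), DeLong structural-component variance
for normal-approximation AUC confidence intervals, and detection rate
(sensitivity) at a fixed false-positive rate with a stratified-bootstrap
percentile interval.  Sensitivity at a fixed FPR uses the step-function
convention: the TPR at the most liberal threshold whose empirical FPR does
not exceed the target, with no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


@dataclass
class EvalResult:
    """AUC, CIs and ROC points for one outcome at one landmark."""

    outcome: str
    landmark_week: int
    n_cases: int
    n_controls: int
    auc: float
    auc_ci: tuple[float, float]
    sens_at_fpr10: float
    sens_ci: tuple[float, float]
    roc_points: np.ndarray  # columns (fpr, tpr, threshold)


def roc_curve(scores, labels) -> np.ndarray:
    """Empirical ROC points ``(fpr, tpr, threshold)`` from grouped thresholds.

    Starts at (0, 0) with threshold +inf and ends at (1, 1); equal scores
    form a single step.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # indices where a new (lower) distinct score starts the next group
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = tp / labels.sum()
    fpr = fp / (~labels).sum()
    thr = s[distinct]
    return np.column_stack(
        [np.r_[0.0, fpr], np.r_[0.0, tpr], np.r_[np.inf, thr]]
    )


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score_case > score_control) + 1/2 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance via structural components (midranks)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    x, ycls = scores[labels], scores[~labels]
    m, n = len(x), len(ycls)
    rx = rankdata(np.r_[x, ycls])[:m]
    ry = rankdata(np.r_[x, ycls])[m:]
    rx_in = rankdata(x)
    ry_in = rankdata(ycls)
    a = float((rx.sum() - m * (m + 1) / 2) / (m * n))
    v10 = (rx - rx_in) / n  # per-case structural component
    v01 = 1.0 - (ry - ry_in) / m  # per-control structural component
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return a, s10 / m + s01 / n


def auc_ci_delong(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation AUC confidence interval with DeLong variance.

    Degenerate variance (e.g. perfect separation) yields a zero-width
    interval at the point estimate.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need >= 2 cases and >= 2 controls")
    a, var = _delong_variance(scores, labels)
    if var <= 0:
        return (a, a)
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (float(max(0.0, a - half)), float(min(1.0, a + half)))


def sensitivity_at_fpr(
    scores,
    labels,
    fpr_target: float = 0.10,
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Detection rate at a fixed false-positive rate, with bootstrap CI.

    The threshold is the most liberal one whose empirical FPR is <= the
    target (no interpolation).  The CI is a percentile interval over
    ``n_boot`` case/control-stratified bootstrap resamples; pass
    ``n_boot=0`` to skip it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    if fpr_target < 0:
        raise ValueError("fpr_target must be >= 0")

    def _sens(case_counts: np.ndarray, ctrl_counts: np.ndarray) -> float:
        # counts per distinct descending threshold; step ROC on cumulative sums
        tp = np.cumsum(case_counts)
        fp = np.cumsum(ctrl_counts)
        tpr = tp / tp[-1]
        fpr = fp / fp[-1]
        ok = fpr <= fpr_target
        return float(tpr[ok].max()) if ok.any() else 0.0

    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    group = np.cumsum(np.r_[True, np.diff(s) != 0]) - 1  # group id per row
    k = group[-1] + 1
    case_counts = np.bincount(group[y], minlength=k)
    ctrl_counts = np.bincount(group[~y], minlength=k)
    sens = _sens(case_counts, ctrl_counts)

    if n_boot <= 0:
        return sens, (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    m, n = int(y.sum()), int((~y).sum())
    p_case = case_counts / m
    p_ctrl = ctrl_counts / n
    boots = np.empty(n_boot)
    for b in range(n_boot):
        cc = rng.multinomial(m, p_case)
        nc = rng.multinomial(n, p_ctrl)
        boots[b] = _sens(cc, nc)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return sens, (float(lo), float(hi))


def evaluate_scores(
    outcome: str,
    landmark_week: int,
    scores,
    labels,
    n_boot: int = 2000,
    seed: int | None = None,
) -> EvalResult:
    """Full ROC summary for one outcome x landmark cell."""
    labels = np.asarray(labels, dtype=bool)
    sens, sens_ci = sensitivity_at_fpr(scores, labels, 0.10, n_boot=n_boot, seed=seed)
    return EvalResult(
        outcome=outcome,
        landmark_week=landmark_week,
        n_cases=int(labels.sum()),
        n_controls=int((~labels).sum()),
        auc=auc(scores, labels),
        auc_ci=auc_ci_delong(scores, labels),
        sens_at_fpr10=sens,
        sens_ci=sens_ci,
        roc_points=roc_curve(scores, labels),
    )


def evaluate_all(
    risk_models: dict,
    datasets: dict,
    n_boot: int = 2000,
    seed: int | None = None,
    eval_ids=None,
) -> tuple[list[EvalResult], list[dict]]:
    """Evaluate every fitted (outcome, landmark) cell.

    ``risk_models`` maps ``(outcome, landmark_week)`` to a fitted risk model
    and ``datasets`` maps ``landmark_week`` to the corresponding landmark
    dataset; ``eval_ids`` optionally restricts evaluation to a subject subset
    (holdout).  Cells that cannot be evaluated are recorded in the returned
    ``missing`` list, never silently skipped.
    """
    from pelandmark import landmark as lm

    results: list[EvalResult] = []
    missing: list[dict] = []
    for (outcome, week), model in risk_models.items():
        ds = datasets[week]
        if eval_ids is not None:
            keep = ds.X.index.intersection(eval_ids)
            ds = lm.LandmarkDataset(ds.landmark_week, ds.X.loc[keep], ds.labels.loc[keep], ds.encoding_metadata)
        labels = ds.labels[outcome].to_numpy(dtype=bool)
        if labels.sum() < 2 or (~labels).sum() < 2:
            missing.append(
                {
                    "outcome": outcome,
                    "landmark_week": week,
                    "error": "too few evaluation cases",
                }
            )
            continue
        scores = lm.predict_risk(model, ds).to_numpy()
        results.append(
            evaluate_scores(outcome, week, scores, labels, n_boot=n_boot, seed=seed)
        )
    return results, missing


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    """One row per outcome x landmark, shaped like a performance table."""
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.outcome,
                "landmark_week": r.landmark_week,
                "auc": r.auc,
                "auc_lo": r.auc_ci[0],
                "auc_hi": r.auc_ci[1],
                "sens_at_fpr10": r.sens_at_fpr10,
                "sens_lo": r.sens_ci[0],
                "sens_hi": r.sens_ci[1],
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
            }
        )
    return pd.DataFrame(rows)
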
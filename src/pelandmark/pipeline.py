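"""Configuration-driven orchestration: simulate → trajectories → features →
risk models → evaluation.

A single global seed is fanned out to per-stage substreams by stable
derivation (CRC32 of the stage name mixed into a ``SeedSequence``), so e.g.
changing the landmark list does not perturb cohort generation.  Every stage
writes its artifact under the output directory and can reload it
(``resume=True``), and a manifest records the config hash, seed, package
versions and stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import pelandmark
from pelandmark import cohort as cm
from pelandmark import evaluation as ev
from pelandmark import features as ft
from pelandmark import landmark as lm
from pelandmark import synth
from pelandmark import trajectory as tj

log = logging.getLogger("pelandmark")

DEFAULT_LANDMARKS = (24, 28, 32, 34, 36)
DEFAULT_OUTCOMES = ("any_pe", "preterm_pe", "term_pe")


class PipelineDataError(RuntimeError):
    """A stage failed on its input data; the message names the stage."""


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream seed (< 2**31), independent of stage order."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable to YAML."""

    generator: synth.GeneratorConfig | None = None
    subjects_path: str | None = None
    visits_path: str | None = None
    landmarks: tuple[int, ...] = DEFAULT_LANDMARKS
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    exclude_aspirin: bool = False
    holdout: bool = False
    output_dir: str = "pelandmark_run"
    seed: int = 0
    n_boot: int = 2000
    trajectory_fit_max_subjects: int | None = None
    resume: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.generator is None and not (self.subjects_path and self.visits_path):
            raise ValueError("need either a generator config or cohort CSV paths")
        bad = set(self.outcomes) - set(lm.OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcomes {sorted(bad)}")
        if any(w < 0 for w in self.landmarks):
            raise ValueError("landmark weeks must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = synth.GeneratorConfig.from_dict(d["generator"])
        cfg = cls(**d)
        cfg.landmarks = tuple(cfg.landmarks)
        cfg.outcomes = tuple(cfg.outcomes)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    subjects: pd.DataFrame
    visits: pd.DataFrame
    trajectory_models: dict[str, tj.TrajectoryModel]
    scales: dict[int, dict[str, ft.UScoreScale]]
    datasets: dict[int, lm.LandmarkDataset]
    risk_models: dict[tuple[str, int], lm.RiskModel]
    results: pd.DataFrame
    manifest: dict


def _subset_dataset(ds: lm.LandmarkDataset, ids: pd.Index) -> lm.LandmarkDataset:
    keep = ds.X.index.intersection(ids)
    return lm.LandmarkDataset(ds.landmark_week, ds.X.loc[keep], ds.labels.loc[keep], ds.encoding_metadata)


def _stage_cohort(config: RunConfig, out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    spath, vpath = out / "subjects.csv", out / "visits.csv"
    if config.generator is not None:
        if config.resume and spath.exists() and vpath.exists():
            return cm.load_cohort(spath, vpath)
        gen = synth.GeneratorConfig.from_dict(config.generator.to_dict())
        gen.seed = derive_seed(config.seed, "cohort")
        bundle = synth.simulate_cohort(gen)
        cm.write_cohort(bundle.subjects, bundle.visits, out)
        bundle.truth.to_csv(out / "truth.csv", index=False)
        subjects, visits = cm.load_cohort(spath, vpath)
    else:
        subjects, visits = cm.load_cohort(config.subjects_path, config.visits_path)
    report = cm.validate_cohort(subjects, visits)
    if not report.ok:
        raise PipelineDataError(
            f"stage cohort: {len(report.violations)} validation violations, "
            f"first: {report.violations[0]}"
        )
    return subjects, visits


def _stage_trajectories(
    config: RunConfig, subjects: pd.DataFrame, visits: pd.DataFrame, out: Path
) -> dict[str, tj.TrajectoryModel]:
    mdir = out / "trajectories"
    mdir.mkdir(exist_ok=True)
    nonpe = subjects[~subjects["pe"]]
    cap = config.trajectory_fit_max_subjects
    if cap is not None and len(nonpe) > cap:
        rng = np.random.default_rng(derive_seed(config.seed, "trajectory_subsample"))
        keep = rng.choice(nonpe["subject_id"].to_numpy(), size=cap, replace=False)
        nonpe = nonpe[nonpe["subject_id"].isin(keep)]
    fit_visits = visits[visits["subject_id"].isin(nonpe["subject_id"])]
    models = {}
    for marker in cm.CONTINUOUS_MARKERS:
        path = mdir / f"{marker}.json"
        if config.resume and path.exists():
            models[marker] = tj.TrajectoryModel.from_json(path)
            continue
        models[marker] = tj.fit_population_trajectory(nonpe, fit_visits, marker)
        models[marker].to_json(path)
        log.info(
            "trajectory %s: n_obs=%d resid_sd=%.2f",
            marker,
            models[marker].fit_n_obs,
            models[marker].residual_sd,
        )
    return models


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage; deterministic given config + seed."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "pipeline.log")
    log.addHandler(fh)
    timings: dict[str, float] = {}
    manifest: dict = {"seed": config.seed, "stages": timings}

    try:
        t0 = time.time()
        subjects, visits = _stage_cohort(config, out)
        timings["cohort"] = round(time.time() - t0, 2)
        log.info("cohort: %d subjects, %d visits", len(subjects), len(visits))

        t0 = time.time()
        models = _stage_trajectories(config, subjects, visits, out)
        timings["trajectories"] = round(time.time() - t0, 2)

        # holdout split (evaluation on held-out subjects when requested)
        if config.holdout:
            rng = np.random.default_rng(derive_seed(config.seed, "holdout"))
            ids = subjects["subject_id"].to_numpy()
            train_mask = rng.uniform(size=len(ids)) < 0.5
            train_ids = pd.Index(ids[train_mask])
            eval_ids = pd.Index(ids[~train_mask])
        else:
            train_ids = eval_ids = pd.Index(subjects["subject_id"])

        t0 = time.time()
        scales: dict[int, dict[str, ft.UScoreScale]] = {}
        datasets: dict[int, lm.LandmarkDataset] = {}
        nonpe_ids = set(subjects.loc[~subjects["pe"], "subject_id"])
        fdir = out / "features"
        fdir.mkdir(exist_ok=True)
        for week in config.landmarks:
            riskset = lm.build_riskset(subjects, week, config.exclude_aspirin)
            raw = ft.compute_raw_features(visits, models, week, subject_ids=riskset)
            scale_ids = raw.index[
                raw.index.isin(nonpe_ids) & raw.index.isin(train_ids)
            ]
            wk_scales: dict[str, ft.UScoreScale] = {}
            for marker in cm.CONTINUOUS_MARKERS:
                try:
                    wk_scales[marker] = ft.fit_uscore_scale(
                        raw.loc[scale_ids], marker, week
                    )
                except ft.UScoreScaleError as exc:
                    log.info("week %d: no u-score scale for %s (%s)", week, marker, exc)
            scales[week] = wk_scales
            uscores = ft.compute_uscores(raw, wk_scales)
            categorical = ft.compute_categorical_features(visits, week)
            ds = lm.assemble_design(subjects, riskset, uscores, categorical, week)
            datasets[week] = ds
            feat = uscores.join(categorical, how="left").join(
                raw[[c for c in raw.columns if c.endswith("_n_obs")]]
            )
            feat.to_csv(fdir / f"week{week}.csv")
            log.info("week %d: risk set %d", week, len(riskset))
        timings["features"] = round(time.time() - t0, 2)

        t0 = time.time()
        risk_models: dict[tuple[str, int], lm.RiskModel] = {}
        missing: list[dict] = []
        for outcome in config.outcomes:
            odir = out / "models" / outcome
            odir.mkdir(parents=True, exist_ok=True)
            for week in config.landmarks:
                path = odir / f"week{week}.json"
                try:
                    if config.resume and path.exists():
                        model = lm.RiskModel.from_json(path)
                    else:
                        model = lm.fit_risk_model(
                            _subset_dataset(datasets[week], train_ids), outcome
                        )
                        model.to_json(path)
                    risk_models[(outcome, week)] = model
                except lm.RiskModelError as exc:
                    missing.append(
                        {"outcome": outcome, "landmark_week": week, "error": str(exc)}
                    )
                    log.warning("skipping %s week %d: %s", outcome, week, exc)
        timings["risk_models"] = round(time.time() - t0, 2)

        t0 = time.time()
        boot_seed = derive_seed(config.seed, "bootstrap")
        results, missing_eval = ev.evaluate_all(
            risk_models,
            datasets,
            n_boot=config.n_boot,
            seed=boot_seed,
            eval_ids=eval_ids if config.holdout else None,
        )
        missing.extend(missing_eval)
        for r in results:
            np.savetxt(
                out / f"roc_{r.outcome}_w{r.landmark_week}.csv",
                r.roc_points,
                delimiter=",",
                header="fpr,tpr,threshold",
                comments="",
            )
        table = ev.results_table(results)
        for cell in missing:  # absent cells are recorded, not silently skipped
            table = pd.concat(
                [table, pd.DataFrame([cell])], ignore_index=True
            )
        table.to_csv(out / "results.csv", index=False)
        timings["evaluation"] = round(time.time() - t0, 2)

        cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        manifest.update(
            {
                "config": config.to_dict(),
                "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
                "versions": {
                    "pelandmark": pelandmark.__version__,
                    "numpy": np.__version__,
                    "pandas": pd.__version__,
                },
                "n_subjects": int(len(subjects)),
                "n_visits": int(len(visits)),
                "riskset_sizes": {int(w): int(len(d.X)) for w, d in datasets.items()},
                "cases_per_outcome": {
                    o: int(lm.classify_outcomes(subjects)[o].sum())
                    for o in config.outcomes
                },
                "missing_cells": missing,
            }
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return RunResult(
            subjects=subjects,
            visits=visits,
            trajectory_models=models,
            scales=scales,
            datasets=datasets,
            risk_models=risk_models,
            results=table,
            manifest=manifest,
        )
    except (cm.CohortLoadError, PipelineDataError):
        raise
    except (tj.TrajectoryFitError, lm.RiskModelError) as exc:
        raise PipelineDataError(f"stage failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
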
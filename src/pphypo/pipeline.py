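"""End-to-end experiment orchestration.

Flow: load or simulate a cohort -> fill short sensor gaps -> filter meal
announcements -> extract (CGM, RIG, GRC, label) samples -> 5-fold
cross-subject validation -> per fold: FN cost, grid search, cost-sensitive
fit, prediction -> sample- and event-level metrics -> per-fold and
mean (SD) summary tables.  Fully deterministic given the experiment seed:
one global seed fans out to per-stage child seeds (cohort, folds, grid
search, learners) so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cgm_io, event_metrics, features, synthetic, training
from .cgm_io import CGMSeries, MealAnnouncement
from .event_metrics import EventMetrics, SampleMetrics
from .training import FoldSplit, TrainedModel

METRIC_COLUMNS = [
    "sens", "spec", "precision", "f1", "auc",
    "NH", "TP_e", "FP_e", "FAR", "DT",
    "severe_alarmed", "severe_missed", "near_hypo_fa_frac",
]


@dataclass
class ExperimentConfig:
    """Everything a run needs; defaults mirror the study protocol."""

    input_csv: str | None = None
    cohort: synthetic.CohortConfig | None = None
    families: tuple[str, ...] = training.FAMILIES
    grids: Mapping[str, list[dict]] | None = None
    k: int = 5
    inner_k: int = 3
    feature_subset: str = "all"
    threshold: float = training.DECISION_THRESHOLD
    window_steps: int = cgm_io.WINDOW_STEPS
    horizon: int = features.HORIZON_STEPS
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.horizon + self.window_steps > 48:
            raise ValueError("horizon + window steps must be <= 48 grid steps")
        if self.input_csv is None and self.cohort is None:
            self.cohort = synthetic.CohortConfig(seed=self.seed)


@dataclass
class FoldReport:
    fold: int
    family: str
    sample: SampleMetrics
    confusion: event_metrics.ConfusionCounts
    event: EventMetrics
    hyperparams: dict
    cost_fn: float
    n_train: int
    n_test: int

    def row(self) -> dict:
        e = self.event
        return {
            "fold": self.fold,
            "family": self.family,
            "sens": self.sample.sensitivity,
            "spec": self.sample.specificity,
            "precision": self.sample.precision,
            "f1": self.sample.f1,
            "auc": self.sample.auc,
            "NH": e.nh,
            "TP_e": e.tp_e,
            "FP_e": e.fp_e,
            "FAR": e.far,
            "DT": e.dt,
            "severe_alarmed": e.severe_alarmed,
            "severe_missed": e.severe_missed,
            "near_hypo_fa_frac": e.near_hypo_fa_frac,
            "cost_fn": self.cost_fn,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "hyperparams": json.dumps(self.hyperparams, sort_keys=True),
        }


@dataclass
class ExperimentResult:
    reports: list[FoldReport]
    folds: list[FoldSplit]
    samples: pd.DataFrame
    skip_log: dict
    models: list[TrainedModel] = field(default_factory=list)

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.reports])

    def summary_frame(self) -> pd.DataFrame:
        """Mean and SD across folds per family; NaN fold values (undefined
        ratios) are omitted from the averages."""
        df = self.folds_frame()
        rows = []
        for family, grp in df.groupby("family", sort=False):
            row: dict = {"family": family, "n_folds": len(grp)}
            for col in METRIC_COLUMNS:
                vals = grp[col].to_numpy(dtype=float)
                vals = vals[~np.isnan(vals)]
                row[f"{col}_mean"] = float(np.mean(vals)) if vals.size else math.nan
                row[f"{col}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan
            rows.append(row)
        return pd.DataFrame(rows)


def _load_series(config: ExperimentConfig) -> list[CGMSeries]:
    if config.input_csv is not None:
        return cgm_io.read_cgm_csv(config.input_csv)
    assert config.cohort is not None
    series, _truth = synthetic.simulate_cohort(config.cohort)
    return series


def preprocess(
    series_list: Sequence[CGMSeries],
) -> tuple[list[CGMSeries], dict[str, list[MealAnnouncement]]]:
    """Gap interpolation then meal filtering, with series context on error."""
    out: list[CGMSeries] = []
    meals: dict[str, list[MealAnnouncement]] = {}
    for s in series_list:
        try:
            filled = cgm_io.interpolate_gaps(s)
        except cgm_io.PreprocessingError as err:
            raise cgm_io.PreprocessingError(
                f"stage=interpolate_gaps series={s.series_id!r}: {err}"
            ) from err
        out.append(filled)
        meals[s.series_id] = cgm_io.filter_meal_announcements(filled)
    return out, meals


def _evaluate_fold_events(
    model: TrainedModel,
    test_samples: pd.DataFrame,
    hard: np.ndarray,
    series_map: Mapping[str, CGMSeries],
    meals: Mapping[str, Sequence[MealAnnouncement]],
) -> EventMetrics:
    """Event/alarm accounting pooled over the fold's test series."""
    test = test_samples.assign(pred=hard)
    all_events: list[event_metrics.HypoEvent] = []
    all_alarms: list[event_metrics.AlarmRecord] = []
    for sid in sorted(test["series_id"].unique()):
        series = series_map[sid]
        ev = event_metrics.extract_hypo_events(series, meals[sid])
        all_events.extend(ev)
        by_meal = {m.meal_index: m for m in meals[sid]}
        for mj, grp in test[test["series_id"] == sid].groupby("meal_index"):
            preds = dict(zip(grp["t"].astype(int), grp["pred"].astype(int)))
            all_alarms.extend(
                event_metrics.detect_alarms(preds, sid, by_meal[mj], events=ev)
            )
    m = event_metrics.match_alarms_events(all_alarms, all_events)
    m.near_hypo_fa_frac = event_metrics.near_hypo_false_alarm_fraction(
        m.false_alarms, series_map
    )
    return m


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full experiment; see the module docstring for the flow."""
    t0 = time.time()
    log: list[dict] = []
    seed_rng = np.random.default_rng(config.seed)
    fold_seed = int(seed_rng.integers(2**31))
    grid_seed = int(seed_rng.integers(2**31))
    model_seed = int(seed_rng.integers(2**31))

    raw_series = _load_series(config)
    series_list, meals = preprocess(raw_series)
    series_map = {s.series_id: s for s in series_list}
    log.append({"stage": "preprocess", "n_series": len(series_list),
                "n_meals": sum(len(v) for v in meals.values())})

    samples, skip_log = features.build_dataset(
        series_list, meals, config.feature_subset, config.window_steps, config.horizon
    )
    log.append({"stage": "features", "n_samples": len(samples),
                "n_pos": int(samples["label"].sum()), **skip_log})

    patients_by_series = {s.series_id: s.patient_id for s in series_list}
    folds = training.cross_subject_folds(patients_by_series, k=config.k, seed=fold_seed)

    grids = config.grids or training.DEFAULT_GRIDS
    reports: list[FoldReport] = []
    models: list[TrainedModel] = []
    for split in folds:
        train = samples[samples["series_id"].isin(split.train_series)]
        test = samples[samples["series_id"].isin(split.test_series)]
        cost = training.compute_fn_cost(train)
        for family in config.families:
            hp = training.grid_search(
                family, train, patients_by_series,
                grid=grids.get(family), inner_k=config.inner_k,
                feature_subset=config.feature_subset, seed=grid_seed,
            )
            model = training.train_model(
                family, train, cost, hp, config.feature_subset, seed=model_seed
            )
            scores, hard = training.predict(model, test, config.threshold)
            confusion, sm = event_metrics.sample_metrics(
                test["label"].to_numpy(dtype=int), hard, scores
            )
            em = _evaluate_fold_events(model, test, hard, series_map, meals)
            reports.append(
                FoldReport(
                    fold=split.fold, family=family, sample=sm, confusion=confusion,
                    event=em, hyperparams=hp, cost_fn=cost.fn_weight,
                    n_train=len(train), n_test=len(test),
                )
            )
            models.append(model)
            log.append({"stage": "fold", "fold": split.fold, "family": family,
                        "hyperparams": hp, "cost_fn": cost.fn_weight,
                        "elapsed_s": round(time.time() - t0, 2)})

    result = ExperimentResult(
        reports=reports, folds=folds, samples=samples, skip_log=skip_log, models=models
    )
    if config.output_dir is not None:
        _write_outputs(config, result, log)
    return result


def _write_outputs(
    config: ExperimentConfig, result: ExperimentResult, log: list[dict]
) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.folds_frame().to_csv(out / "folds.csv", index=False)
    result.summary_frame().to_csv(out / "summary.csv", index=False)
    (out / "models").mkdir(exist_ok=True)
    for model, r in zip(result.models, result.reports):
        manifest = {
            "family": r.family,
            "fold": r.fold,
            "hyperparameters": r.hyperparams,
            "cost_fn": r.cost_fn,
            "feature_subset": model.feature_subset,
            "scaler_min": model.scaler.minima,
            "scaler_max": model.scaler.maxima,
        }
        (out / "models" / f"fold{r.fold}_{r.family}.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1)
        )
    with open(out / "log.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def compare_runs(a: ExperimentResult, b: ExperimentResult) -> pd.DataFrame:
    """Per-fold paired metric differences (a minus b), with mean deltas.

    Both runs must share the fold structure (e.g. the feature-ablation
    comparison on identical cohort and seeds).
    """
    fa, fb = a.folds_frame(), b.folds_frame()
    if list(fa["fold"]) != list(fb["fold"]) or list(fa["family"]) != list(fb["family"]):
        raise ValueError("runs have mismatched fold/family structure")
    rows = []
    for (_, ra), (_, rb) in zip(fa.iterrows(), fb.iterrows()):
        row = {"fold": ra["fold"], "family": ra["family"]}
        for col in METRIC_COLUMNS:
            row[f"d_{col}"] = ra[col] - rb[col]
        rows.append(row)
    deltas = pd.DataFrame(rows)
    means = {"fold": "mean", "family": "all"}
    for col in METRIC_COLUMNS:
        means[f"d_{col}"] = float(np.nanmean(deltas[f"d_{col}"].to_numpy(dtype=float)))
    return pd.concat([deltas, pd.DataFrame([means])], ignore_index=True)
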
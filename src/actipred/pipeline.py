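"""End-to-end orchestration: simulate → features → windows → CV → evaluate.

The pipeline fuses cohort simulation with feature extraction day by day
(a full patient's raw stream at 20 Hz does not fit comfortably in
memory), then builds labeled 7-day windows, cross-validates the SGD
logistic-regression classifier on blocked folds, predicts each window
out-of-fold, and scores both evaluation views.

A label-permutation null is available for signal-detection checks: the
cross-validated window predictions are held fixed while each patient's
readmission dates are re-drawn uniformly over the observation period,
destroying any prediction/event association while preserving event
counts and the prediction pattern.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluate, features, model, synth, windows

logger = logging.getLogger("actipred")

__all__ = ["RunConfig", "PipelineResult", "simulate_daily_features", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a pipeline run.

    Every constant of the analysis that is not forced by the method
    itself lives here: wear-gap limit, lookahead horizon, window length,
    guard gap, SGD hyperparameters, decision threshold, fold count.
    """

    cohort: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    max_gap_seconds: float | None = None
    horizon: int = 30
    window_length: int = 7
    guard_gap: int = 6
    k_folds: int = 10
    learning_rate: float = 0.01
    n_epochs: int = 200
    tol: float = 1e-6
    threshold: float = 0.5
    seed: int = 0
    permutation_reps: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = synth.CohortConfig.from_dict(d.pop("cohort", {}) or {})
        known = {f.name for f in dataclasses.fields(cls)} - {"cohort"}
        return cls(cohort=cohort, **{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PipelineResult:
    config: RunConfig
    event_logs: dict[str, synth.EventLog]
    daily: dict[str, list[features.DailyFeatures]]
    labeled: list[windows.LabeledWindow]
    valid_idx: np.ndarray
    folds: list[np.ndarray]
    cv: model.CVResult
    predicted: np.ndarray  # bool per evaluated valid window
    evaluated_idx: np.ndarray  # indices (into valid windows) with oof preds
    report: evaluate.EvaluationReport
    null_precisions: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return len(self.labeled)

    @property
    def n_valid(self) -> int:
        return len(self.valid_idx)


def simulate_daily_features(
    config: synth.CohortConfig,
    max_gap_seconds: float | None = None,
) -> tuple[dict[str, list[features.DailyFeatures]], dict[str, synth.EventLog]]:
    """Generate the cohort and reduce it to daily features, day by day."""
    daily: dict[str, list[features.DailyFeatures]] = {}
    logs: dict[str, synth.EventLog] = {}
    for i, pid in enumerate(synth.patient_ids(config)):
        log, days = synth.iter_patient_days(config, pid, i)
        feats: list[features.DailyFeatures] = []
        prev = None
        for rec in days:
            f = features.day_features(
                rec,
                pid,
                config.sampling_rate,
                prev=prev,
                max_gap_seconds=max_gap_seconds,
            )
            feats.append(f)
            prev = f
        daily[pid] = feats
        logs[pid] = log
        logger.info(
            "simulated %s: %d days, %d readmissions",
            pid,
            len(feats),
            len(log.readmission_dates),
        )
    return daily, logs


def build_labeled_windows(
    daily: Mapping[str, list[features.DailyFeatures]],
    logs: Mapping[str, synth.EventLog],
    window_length: int = 7,
    horizon: int = 30,
) -> list[windows.LabeledWindow]:
    labeled: list[windows.LabeledWindow] = []
    for pid, feats in daily.items():
        wins = windows.build_windows(feats, logs[pid], window_length)
        labeled.extend(windows.label_window(w, logs[pid], horizon) for w in wins)
    return labeled


def permutation_null_precision(
    labeled_valid: Sequence[windows.LabeledWindow],
    predicted: Sequence[bool],
    logs: Mapping[str, synth.EventLog],
    horizon: int,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Event-based precision under random event placement.

    For each replicate, every patient's readmission dates are re-drawn
    uniformly (without replacement) over the observation period while
    the window predictions stay fixed. Replicates in which no event is
    evaluable yield NaN.
    """
    out = np.full(n_reps, np.nan)
    for r in range(n_reps):
        permuted: dict[str, synth.EventLog] = {}
        for pid, log in logs.items():
            n_days = (log.observation_end - log.observation_start).days + 1
            k = len(log.readmission_dates)
            if k > 0:
                offs = rng.choice(n_days, size=min(k, n_days), replace=False)
                dates = sorted(
                    log.observation_start + dt.timedelta(days=int(o)) for o in offs
                )
            else:
                dates = []
            permuted[pid] = synth.EventLog(
                pid, dates, log.observation_start, log.observation_end
            )
        _, _, prec, _ = evaluate.score_events(
            predicted, labeled_valid, permuted, horizon
        )
        if prec is not None:
            out[r] = prec
    return out


def run_all(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline on a synthetic cohort."""
    logger.info("pipeline start (config %s)", config.config_hash())
    daily, logs = simulate_daily_features(config.cohort, config.max_gap_seconds)

    labeled = build_labeled_windows(
        daily, logs, config.window_length, config.horizon
    )
    valid_idx = np.array(
        [i for i, lw in enumerate(labeled) if lw.validity == "valid"],
        dtype=np.int64,
    )
    labeled_valid = [labeled[int(i)] for i in valid_idx]
    n_pos = sum(lw.label == 1 for lw in labeled_valid)
    logger.info(
        "windows: %d total, %d valid (%d positive, %d negative)",
        len(labeled),
        len(valid_idx),
        n_pos,
        len(valid_idx) - n_pos,
    )

    folds = windows.split_folds(labeled_valid, config.k_folds, config.guard_gap)
    X = windows.feature_matrix(labeled_valid)
    y = np.array([lw.label for lw in labeled_valid], dtype=np.float64)
    cv = model.cross_validate(
        X,
        y,
        folds,
        learning_rate=config.learning_rate,
        n_epochs=config.n_epochs,
        tol=config.tol,
        seed=config.seed,
        threshold=config.threshold,
        feature_names=windows.feature_names(config.window_length),
    )
    logger.info(
        "cross-validation: mean accuracy %.3f, mean log-loss %.4f",
        cv.mean_accuracy,
        cv.mean_log_loss,
    )

    evaluated_idx = np.nonzero(~np.isnan(cv.oof_proba))[0]
    eval_windows = [labeled_valid[int(i)] for i in evaluated_idx]
    predicted = cv.oof_proba[evaluated_idx] >= config.threshold

    tp, fp, _ = evaluate.score_predictions(predicted, eval_windows)
    te, me, _, event_detail = evaluate.score_events(
        predicted, eval_windows, logs, config.horizon
    )
    n_events = sum(len(l.readmission_dates) for l in logs.values())
    window_detail = [
        {
            "patient_id": lw.window.patient_id,
            "last_day": lw.window.last_day.isoformat(),
            "predicted": bool(p),
            "label": lw.label,
        }
        for p, lw in zip(predicted, eval_windows)
    ]
    report = evaluate.build_report(
        n_valid=len(eval_windows),
        n_predicted=int(np.sum(predicted)),
        tp=tp,
        fp=fp,
        te=te,
        me=me,
        n_events_total=n_events,
        n_events_evaluable=te + me,
        per_event_detail=event_detail,
        per_window_detail=window_detail,
    )
    logger.info(
        "evaluation: TP=%d FP=%d TE=%d ME=%d (of %d events)",
        tp,
        fp,
        te,
        me,
        n_events,
    )

    null = None
    if config.permutation_reps > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x5EED])
        )
        null = permutation_null_precision(
            eval_windows,
            predicted,
            logs,
            config.horizon,
            config.permutation_reps,
            rng,
        )

    return PipelineResult(
        config=config,
        event_logs=logs,
        daily=daily,
        labeled=labeled,
        valid_idx=valid_idx,
        folds=folds,
        cv=cv,
        predicted=predicted,
        evaluated_idx=evaluated_idx,
        report=report,
        null_precisions=null,
    )


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the run's artifact tree (CSV/JSON, all text)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = result.config.config_hash()
    paths: dict[str, Path] = {}

    def _with_hash(payload: dict) -> dict:
        payload["config_hash"] = cfg_hash
        return payload

    paths["config"] = out / "run_config.yaml"
    result.config.to_yaml(paths["config"])

    paths["events"] = out / "events.csv"
    synth.write_event_log_csv(list(result.event_logs.values()), paths["events"])
    paths["manifest"] = out / "cohort_manifest.json"
    synth.write_manifest(
        result.config.cohort, list(result.event_logs.values()), paths["manifest"]
    )

    all_daily = [f for feats in result.daily.values() for f in feats]
    paths["daily_features"] = out / "daily_features.csv"
    features.daily_features_to_frame(all_daily).to_csv(
        paths["daily_features"], index=False, float_format="%.6f"
    )

    paths["windows"] = out / "windows.csv"
    windows.labeled_windows_to_frame(result.labeled).to_csv(
        paths["windows"], index=False
    )

    labeled_valid = [result.labeled[int(i)] for i in result.valid_idx]
    fm = windows.feature_matrix(labeled_valid)
    paths["features"] = out / "window_features.csv"
    pd.DataFrame(
        fm, columns=windows.feature_names(result.config.window_length)
    ).to_csv(paths["features"], index=False, float_format="%.6f")

    fold_rows = []
    for j, fold in enumerate(result.folds):
        for i in fold:
            lw = labeled_valid[int(i)]
            fold_rows.append(
                {
                    "patient_id": lw.window.patient_id,
                    "last_day": lw.window.last_day.isoformat(),
                    "fold": j,
                }
            )
    paths["folds"] = out / "folds.csv"
    pd.DataFrame(fold_rows, columns=["patient_id", "last_day", "fold"]).to_csv(
        paths["folds"], index=False
    )

    paths["model"] = out / "model.json"
    result.cv.averaged_model.to_json(paths["model"])

    paths["cv_scores"] = out / "cv_scores.json"
    paths["cv_scores"].write_text(
        json.dumps(
            _with_hash(
                {
                    "fold_log_loss": result.cv.fold_log_loss,
                    "fold_accuracy": result.cv.fold_accuracy,
                    "mean_log_loss": result.cv.mean_log_loss,
                    "mean_accuracy": result.cv.mean_accuracy,
                }
            ),
            indent=2,
            sort_keys=True,
        )
    )

    paths["report"] = out / "report.json"
    paths["report"].write_text(
        json.dumps(
            _with_hash(result.report.to_dict()), indent=2, sort_keys=True
        )
    )

    ev, win = result.report.detail_frames()
    paths["per_event"] = out / "per_event.csv"
    ev.to_csv(paths["per_event"], index=False)
    paths["per_window"] = out / "per_window.csv"
    win.to_csv(paths["per_window"], index=False)

    if result.null_precisions is not None:
        paths["null"] = out / "permutation_null.json"
        obs = result.report.precision_event_based
        finite = result.null_precisions[~np.isnan(result.null_precisions)]
        paths["null"].write_text(
            json.dumps(
                _with_hash(
                    {
                        "observed_precision_pct": obs,
                        "null_precisions_pct": result.null_precisions.tolist(),
                        "null_p95_pct": (
                            float(np.percentile(finite, 95)) if finite.size else None
                        ),
                    }
                ),
                indent=2,
                sort_keys=True,
            )
        )
    return paths
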
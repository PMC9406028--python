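"""Dual evaluation of readmission predictions.

Two complementary views of performance:

* **Prediction-based** — over the valid windows for which the model
  declared a readmission: a true prediction (TP) is followed by an
  actual readmission within 30 days of the window's last day, a false
  prediction (FP) is not.  Accuracy = TP / (TP + FP) × 100; its
  complement is the false prediction rate.

* **Event-based** — over the actual readmission events: an event is
  truly predicted (TE) if at least one window predicted a readmission
  with its last day in the 30 days *prior* to the event
  ([event − 30, event − 1]; a window ending on the event day itself is
  not prior), otherwise it is mispredicted (ME).
  Precision = TE / (TE + ME) × 100.

Undefined ratios (zero denominators) are reported as None, never as 0
or 100. Percentages are rounded to 2 decimals only at serialization.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import EventLog
from .windows import HORIZON_DAYS, LabeledWindow

__all__ = [
    "EvaluationReport",
    "score_predictions",
    "score_events",
    "build_report",
]


@dataclass
class EvaluationReport:
    """Counts and percentages of both evaluation views."""

    n_valid: int
    n_predicted: int
    tp: int
    fp: int
    te: int
    me: int
    n_events_total: int | None = None
    n_events_evaluable: int | None = None
    per_event_detail: list[dict] = field(default_factory=list)
    per_window_detail: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.n_valid, self.n_predicted, self.tp, self.fp, self.te, self.me) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fp != self.n_predicted:
            raise ValueError(
                f"TP + FP = {self.tp + self.fp} must equal "
                f"n_predicted = {self.n_predicted}"
            )
        if self.n_predicted > self.n_valid:
            raise ValueError("cannot predict more windows than are valid")
        if self.n_events_evaluable is not None and (
            self.te + self.me != self.n_events_evaluable
        ):
            raise ValueError("TE + ME must equal the number of evaluable events")
        if (
            self.n_events_evaluable is not None
            and self.n_events_evaluable > 0
            and self.te + self.me == 0
        ):
            raise ValueError("evaluable events present but TE = ME = 0")

    @property
    def accuracy_prediction_based(self) -> float | None:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else None

    @property
    def false_prediction_rate(self) -> float | None:
        a = self.accuracy_prediction_based
        return None if a is None else 100.0 - a

    @property
    def precision_event_based(self) -> float | None:
        d = self.te + self.me
        return 100.0 * self.te / d if d else None

    @property
    def event_miss_rate(self) -> float | None:
        p = self.precision_event_based
        return None if p is None else 100.0 - p

    def to_dict(self) -> dict:
        rnd = lambda v: None if v is None else round(v, 2)
        return {
            "n_valid_datasets": self.n_valid,
            "n_datasets_with_prediction": self.n_predicted,
            "true_predictions": self.tp,
            "false_predictions": self.fp,
            "truly_predicted_events": self.te,
            "mispredicted_events": self.me,
            "n_events_total": self.n_events_total,
            "n_events_evaluable": self.n_events_evaluable,
            "accuracy_prediction_based_pct": rnd(self.accuracy_prediction_based),
            "false_prediction_rate_pct": rnd(self.false_prediction_rate),
            "precision_event_based_pct": rnd(self.precision_event_based),
            "event_miss_rate_pct": rnd(self.event_miss_rate),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def detail_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (
            pd.DataFrame(
                self.per_event_detail,
                columns=["patient_id", "event_date", "truly_predicted", "earliest_window"],
            ),
            pd.DataFrame(
                self.per_window_detail,
                columns=["patient_id", "last_day", "predicted", "label"],
            ),
        )


def score_predictions(
    predicted: Sequence[bool], labeled: Sequence[LabeledWindow]
) -> tuple[int, int, float | None]:
    """Window-level TP/FP counts and prediction-based accuracy.

    ``predicted`` aligns with ``labeled``; all windows must be valid.
    """
    if len(predicted) != len(labeled):
        raise ValueError("predictions must align with windows")
    tp = fp = 0
    for p, lw in zip(predicted, labeled):
        if lw.validity != "valid":
            raise ValueError("predictions are only adjudicated on valid windows")
        if p:
            if lw.label == 1:
                tp += 1
            else:
                fp += 1
    acc = 100.0 * tp / (tp + fp) if (tp + fp) else None
    return tp, fp, acc


def score_events(
    predicted: Sequence[bool],
    labeled: Sequence[LabeledWindow],
    events: Mapping[str, EventLog],
    horizon: int = HORIZON_DAYS,
) -> tuple[int, int, float | None, list[dict]]:
    """Event-level TE/ME counts and event-based precision.

    An event is evaluable when at least one valid window (predicted or
    not) ends within its ``horizon``-day pre-window; events with no
    observable pre-window are excluded from the denominator and flagged
    in the detail list.
    """
    if len(predicted) != len(labeled):
        raise ValueError("predictions must align with windows")
    by_patient: dict[str, list[tuple[dt.date, bool]]] = {}
    for p, lw in zip(predicted, labeled):
        by_patient.setdefault(lw.window.patient_id, []).append(
            (lw.window.last_day, bool(p))
        )

    te = me = 0
    detail: list[dict] = []
    for pid, log in events.items():
        wins = by_patient.get(pid, [])
        for event in log.readmission_dates:
            lo = event - dt.timedelta(days=horizon)
            hi = event - dt.timedelta(days=1)
            in_pre = [(d, p) for d, p in wins if lo <= d <= hi]
            predicted_days = sorted(d for d, p in in_pre if p)
            entry = {
                "patient_id": pid,
                "event_date": event.isoformat(),
                "truly_predicted": bool(predicted_days),
                "earliest_window": (
                    predicted_days[0].isoformat() if predicted_days else ""
                ),
            }
            if not in_pre:
                entry["truly_predicted"] = None  # not evaluable
                detail.append(entry)
                continue
            if predicted_days:
                te += 1
            else:
                me += 1
            detail.append(entry)
    precision = 100.0 * te / (te + me) if (te + me) else None
    return te, me, precision, detail


def build_report(
    n_valid: int,
    n_predicted: int,
    tp: int,
    fp: int,
    te: int,
    me: int,
    n_events_total: int | None = None,
    n_events_evaluable: int | None = None,
    per_event_detail: list[dict] | None = None,
    per_window_detail: list[dict] | None = None,
) -> EvaluationReport:
    """Assemble a consistency-checked report from the raw counts."""
    if n_events_evaluable is None and (te or me):
        n_events_evaluable = te + me
    return EvaluationReport(
        n_valid=n_valid,
        n_predicted=n_predicted,
        tp=tp,
        fp=fp,
        te=te,
        me=me,
        n_events_total=n_events_total,
        n_events_evaluable=n_events_evaluable,
        per_event_detail=per_event_detail or [],
        per_window_detail=per_window_detail or [],
    )
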
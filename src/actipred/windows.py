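"""Sliding 7-day PA datasets with 30-day-lookahead readmission labels.

A *dataset* (here: window) is 7 consecutive wear-valid days of daily
features from one patient. Windows slide by one day, so consecutive
windows overlap on 6 days. Each window targets the day after its last
day; it is

* **valid** if clinical follow-up is known for the full 30 days after
  the last day (otherwise the prediction could not be adjudicated),
* **positive** if an actual readmission occurred within those 30 days,
* **negative** otherwise.

For cross-validation the windows are grouped into contiguous time
blocks (blocked k-fold): because overlapping windows share days, a
random split would leak test-day information into training. Blocks are
separated by a guard gap of ``window_length − 1`` days so that no
calendar day of any patient appears on both sides of a train/test
boundary.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import DailyFeatures
from .synth import EventLog

WINDOW_LENGTH = 7
HORIZON_DAYS = 30
GUARD_GAP_DAYS = WINDOW_LENGTH - 1

#: ordering of the per-day block of the feature vector
DAY_FEATURE_NAMES = ("ai_sum", "ai_mean", "ai_median", "ai_cov", "ri", "qoa")
AGGREGATE_FEATURE_NAMES = (
    "agg_ai_sum_mean",
    "agg_ai_sum_cov",
    "agg_ri_mean",
    "agg_qoa_mean",
    "agg_ai_sum_slope",
    "agg_qoa_slope",
)


def feature_names(window_length: int = WINDOW_LENGTH) -> list[str]:
    names = [
        f"day{d + 1}_{name}"
        for d in range(window_length)
        for name in DAY_FEATURE_NAMES
    ]
    names.extend(AGGREGATE_FEATURE_NAMES)
    return names


@dataclass
class PAWindow:
    """Seven consecutive wear-valid days of one patient's features."""

    patient_id: str
    day_features: list[DailyFeatures]
    last_day: dt.date
    prediction_date: dt.date

    def __post_init__(self) -> None:
        n = len(self.day_features)
        for i, f in enumerate(self.day_features):
            if not f.wear_valid:
                raise ValueError("every day of a window must be wear-valid")
            expect = self.day_features[0].date + dt.timedelta(days=i)
            if f.date != expect:
                raise ValueError("window days must be consecutive calendar days")
        if self.day_features[-1].date != self.last_day:
            raise ValueError("last_day must match the final day of features")
        if self.prediction_date != self.last_day + dt.timedelta(days=1):
            raise ValueError("prediction_date must be last_day + 1")

    @property
    def first_day(self) -> dt.date:
        return self.day_features[0].date

    def day_set(self) -> set[dt.date]:
        return {f.date for f in self.day_features}


@dataclass
class LabeledWindow:
    """A window with its validity, label, and numeric feature vector."""

    window: PAWindow
    validity: str  # "valid" | "invalid"
    label: int | None  # 1 positive, 0 negative, None if invalid
    matched_event: dt.date | None
    feature_vector: np.ndarray

    def __post_init__(self) -> None:
        if (self.label is not None) != (self.validity == "valid"):
            raise ValueError("label is defined exactly for valid windows")


def build_windows(
    daily: Sequence[DailyFeatures],
    events: EventLog | None = None,
    window_length: int = WINDOW_LENGTH,
) -> list[PAWindow]:
    """All stride-1 windows over runs of consecutive wear-valid days.

    Days on which a readmission occurred break the runs (together with
    the non-wear in-hospital days that follow, this keeps windows from
    spanning a hospitalization).
    """
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    days = sorted(daily, key=lambda f: f.date)
    for a, b in zip(days, days[1:]):
        if b.date <= a.date:
            raise ValueError("duplicate or unordered daily features")
    event_dates = set(events.readmission_dates) if events is not None else set()

    windows: list[PAWindow] = []
    run: list[DailyFeatures] = []
    for f in days:
        usable = f.wear_valid and f.date not in event_dates
        contiguous = bool(run) and f.date == run[-1].date + dt.timedelta(days=1)
        if not usable:
            run = []
            continue
        run = run + [f] if contiguous else [f]
        if len(run) >= window_length:
            block = run[-window_length:]
            windows.append(
                PAWindow(
                    patient_id=block[0].patient_id,
                    day_features=block,
                    last_day=block[-1].date,
                    prediction_date=block[-1].date + dt.timedelta(days=1),
                )
            )
    return windows


def label_window(
    w: PAWindow, events: EventLog, horizon: int = HORIZON_DAYS
) -> LabeledWindow:
    """Adjudicate a window under the ``horizon``-day lookahead rule.

    Valid iff follow-up covers ``last_day + horizon``; positive iff a
    readmission falls in the half-open-left interval
    ``(last_day, last_day + horizon]`` — an event on the last recorded
    day is not a future readmission, an event on day 30 counts.
    """
    if events.patient_id != w.patient_id:
        raise ValueError(
            f"event log is for {events.patient_id}, window for {w.patient_id}"
        )
    fv = featurize(w)
    if w.last_day + dt.timedelta(days=horizon) > events.observation_end:
        return LabeledWindow(w, "invalid", None, None, fv)
    lo = w.last_day
    hi = w.last_day + dt.timedelta(days=horizon)
    matched = [d for d in events.readmission_dates if lo < d <= hi]
    if matched:
        return LabeledWindow(w, "valid", 1, min(matched), fv)
    return LabeledWindow(w, "valid", 0, None, fv)


def _slope(y: np.ndarray) -> float:
    """Least-squares slope of y against day index 0..len(y)-1."""
    x = np.arange(len(y), dtype=np.float64)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(xc, y - y.mean()) / denom)


def featurize(w: PAWindow) -> np.ndarray:
    """Numeric feature vector of a window (48 values for 7-day windows).

    Per day: ai_sum, ai_mean, ai_median, ai_cov, RI (0 when undefined),
    QoA — 6 × 7 = 42 values — followed by six cross-window aggregates:
    mean and CoV of daily ai_sum, mean RI, mean QoA, and least-squares
    trend slopes of daily ai_sum and QoA (per day). The trend slopes
    capture the progressive pre-readmission decline that motivates the
    retrospective window design. Standardization is *not* applied here;
    the model standardizes using training-fold statistics only.
    """
    per_day = []
    for f in w.day_features:
        ri = 0.0 if math.isnan(f.ri) else f.ri
        per_day.append((f.ai_sum, f.ai_mean, f.ai_median, f.ai_cov, ri, f.qoa))
    arr = np.asarray(per_day, dtype=np.float64)
    ai_sums = arr[:, 0]
    qoas = arr[:, 5]
    ai_mean = float(ai_sums.mean())
    ai_sd = float(ai_sums.std())
    ai_cov = ai_sd / ai_mean if ai_mean > 0 else 0.0
    aggregates = np.array(
        [
            ai_mean,
            ai_cov,
            float(arr[:, 4].mean()),
            float(qoas.mean()),
            _slope(ai_sums),
            _slope(qoas),
        ],
        dtype=np.float64,
    )
    return np.concatenate([arr.ravel(), aggregates])


@dataclass
class _Run:
    """A maximal block of windows with consecutive last days."""

    indices: list[int]


def _collect_runs(labeled: Sequence[LabeledWindow]) -> list[_Run]:
    order = sorted(
        range(len(labeled)),
        key=lambda i: (labeled[i].window.patient_id, labeled[i].window.last_day),
    )
    runs: list[_Run] = []
    for i in order:
        w = labeled[i].window
        if runs:
            prev = labeled[runs[-1].indices[-1]].window
            if (
                prev.patient_id == w.patient_id
                and w.last_day == prev.last_day + dt.timedelta(days=1)
            ):
                runs[-1].indices.append(i)
                continue
        runs.append(_Run([i]))
    return runs


def _split_run(
    run: _Run, labeled: Sequence[LabeledWindow], guard: int
) -> tuple[_Run, _Run] | None:
    """Cut a run in half with a guard gap; windows straddling the cut
    are dropped so the two halves share no calendar day. Returns None
    if the run is too short to yield two non-empty halves."""
    m = len(run.indices)
    c = m // 2
    left = run.indices[:c]
    right = run.indices[c + guard :]
    if not left or not right:
        return None
    return _Run(left), _Run(right)


def split_folds(
    labeled: Sequence[LabeledWindow],
    k: int = 10,
    guard_gap: int = GUARD_GAP_DAYS,
) -> list[np.ndarray]:
    """Blocked k-fold assignment of windows to disjoint folds.

    Windows are grouped into runs (contiguous last days within a
    patient). If there are fewer runs than folds, the largest runs are
    recursively cut with a ``guard_gap``-day guard (straddling windows
    dropped) until k blocks exist. Runs are then assigned to folds,
    largest first, each to the currently smallest fold — so fold run
    counts stay within ±1. Dropped windows appear in no fold.

    Returns k arrays of indices into ``labeled``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    runs = _collect_runs(labeled)
    runs.sort(key=lambda r: -len(r.indices))
    while len(runs) < k:
        runs.sort(key=lambda r: -len(r.indices))
        halves = _split_run(runs[0], labeled, guard_gap)
        if halves is None:
            raise ValueError(
                f"cannot form {k} blocked folds from {len(runs)} runs: "
                "not enough contiguous windows"
            )
        runs = [halves[0], halves[1]] + runs[1:]

    runs.sort(key=lambda r: -len(r.indices))
    fold_runs: list[list[_Run]] = [[] for _ in range(k)]
    fold_sizes = [0] * k
    for r in runs:
        min_nruns = min(len(fr) for fr in fold_runs)
        candidates = [j for j in range(k) if len(fold_runs[j]) == min_nruns]
        j = min(candidates, key=lambda j: fold_sizes[j])
        fold_runs[j].append(r)
        fold_sizes[j] += len(r.indices)
    folds = [
        np.array(sorted(i for r in fr for i in r.indices), dtype=np.int64)
        for fr in fold_runs
    ]
    if any(len(f) == 0 for f in folds):
        raise ValueError("empty fold; too few windows for blocked k-fold")
    return folds


def fold_day_sets(
    labeled: Sequence[LabeledWindow], fold: np.ndarray
) -> dict[str, set[dt.date]]:
    """Per-patient calendar-day sets covered by a fold's windows."""
    out: dict[str, set[dt.date]] = {}
    for i in fold:
        w = labeled[int(i)].window
        out.setdefault(w.patient_id, set()).update(w.day_set())
    return out


def labeled_windows_to_frame(labeled: Sequence[LabeledWindow]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": lw.window.patient_id,
            "last_day": lw.window.last_day.isoformat(),
            "validity": lw.validity,
            "label": {1: "positive", 0: "negative", None: "none"}[lw.label],
            "matched_event": (
                lw.matched_event.isoformat() if lw.matched_event else ""
            ),
        }
        for lw in labeled
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "last_day", "validity", "label", "matched_event"]
    )


def feature_matrix(labeled: Sequence[LabeledWindow]) -> np.ndarray:
    return np.vstack([lw.feature_vector for lw in labeled])
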
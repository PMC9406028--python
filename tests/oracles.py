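"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a pipeline quantity by the most direct route
possible — nested loops over the defining formulas, exhaustive day
scans — and deliberately shares no code with the implementation it
checks.
"""

from __future__ import annotations

import datetime as dt
import math


def brute_force_minute_ai(
    sample_index, xyz, sampling_rate: float
) -> list[float]:
    """Minute-level Activity Index by direct nested loops.

    For each of the 1440 minutes, for each of its 12 five-second
    epochs: gather the samples of the epoch, compute each resultant
    acceleration, the epoch mean, and the population SD; sum the SDs of
    the epochs that have samples. Minutes with no samples give NaN.
    """
    spe = int(sampling_rate * 5)
    by_epoch: dict[int, list[float]] = {}
    for pos, idx in enumerate(sample_index):
        e = int(idx) // spe
        a = math.sqrt(
            float(xyz[pos][0]) ** 2
            + float(xyz[pos][1]) ** 2
            + float(xyz[pos][2]) ** 2
        )
        by_epoch.setdefault(e, []).append(a)

    out: list[float] = []
    for minute in range(1440):
        total = 0.0
        seen = 0
        for k in range(12):
            e = minute * 12 + k
            vals = by_epoch.get(e)
            if not vals:
                continue
            mu = sum(vals) / len(vals)
            var = sum((v - mu) ** 2 for v in vals) / len(vals)
            total += math.sqrt(var)
            seen += 1
        out.append(total if seen else math.nan)
    return out


def brute_force_hourly(minute_ai: list[float]) -> list[float]:
    out = []
    for h in range(24):
        s = 0.0
        for m in range(60):
            v = minute_ai[h * 60 + m]
            if not math.isnan(v):
                s += v
        out.append(s)
    return out


def brute_force_label(
    last_day: dt.date,
    event_dates: list[dt.date],
    observation_end: dt.date,
    horizon: int = 30,
) -> tuple[str, int | None]:
    """(validity, label) by scanning each following day individually."""
    for offset in range(1, horizon + 1):
        if last_day + dt.timedelta(days=offset) > observation_end:
            return "invalid", None
    for offset in range(1, horizon + 1):
        if last_day + dt.timedelta(days=offset) in event_dates:
            return "valid", 1
    return "valid", 0


def brute_force_event_counts(
    window_preds: list[tuple[str, dt.date, bool]],
    events: dict[str, list[dt.date]],
    horizon: int = 30,
) -> tuple[int, int, int]:
    """(TE, ME, not-evaluable) by exhaustive day scanning.

    ``window_preds``: (patient_id, last_day, predicted) per valid window.
    """
    te = me = skipped = 0
    for pid, dates in events.items():
        for event in dates:
            any_window = False
            any_predicted = False
            for offset in range(1, horizon + 1):
                day = event - dt.timedelta(days=offset)
                for wpid, last, pred in window_preds:
                    if wpid == pid and last == day:
                        any_window = True
                        if pred:
                            any_predicted = True
            if not any_window:
                skipped += 1
            elif any_predicted:
                te += 1
            else:
                me += 1
    return te, me, skipped


def brute_force_prediction_counts(
    window_preds: list[tuple[str, dt.date, bool]],
    events: dict[str, list[dt.date]],
    horizon: int = 30,
) -> tuple[int, int]:
    """(TP, FP) by scanning the lookahead of each predicted window."""
    tp = fp = 0
    for pid, last, pred in window_preds:
        if not pred:
            continue
        hit = False
        for offset in range(1, horizon + 1):
            if last + dt.timedelta(days=offset) in events.get(pid, []):
                hit = True
        if hit:
            tp += 1
        else:
            fp += 1
    return tp, fp
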
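"""Activity-based feature extraction from raw tri-axial accelerometry.

The feature family quantifies daily-living physical activity (PA) from a
wrist-worn accelerometer:

* resultant acceleration ``A_i = sqrt(ax² + ay² + az²)`` per sample;
* per 5-second epoch, the mean ``μ`` and the *population* standard
  deviation ``σ_k`` of the resultant — the SD removes the constant
  gravity component, leaving the quantified PA of the epoch;
* the minute-level Activity Index ``AI = Σ_k σ_k`` over the 12 epochs of
  a minute;
* hourly PA: the sum of the 60 minute-AI values of a clock hour;
* the Regularity Index ``RI``: the Pearson correlation between the 24
  hourly-PA values of consecutive days, measuring routine regularity;
* the daily Quality of Activity ``QoA = (Σ_m AI_m) × (1 + RI)``.

All epochs, minutes, and hours are anchored to the wall clock of the
patient's local day (00:00), and a day enters analysis only if at least
16 h of PA data were recorded over the 24-h period (wear validity).
Missing spans are treated as absent, never as zeros: sums run over the
observed slots only, and per-slot coverage counts are kept so downstream
stages can filter on completeness.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import (
    EPOCH_SECONDS,
    SECONDS_PER_DAY,
    AccelStream,
    DayRecord,
)

EPOCHS_PER_MINUTE = 12
MINUTES_PER_DAY = 1440
EPOCHS_PER_DAY = SECONDS_PER_DAY // EPOCH_SECONDS  # 17280
WEAR_VALID_SECONDS = 16 * 3600

__all__ = [
    "EpochStat",
    "DailyFeatures",
    "resultant_acceleration",
    "epoch_stats",
    "minute_activity_index",
    "hourly_pa",
    "regularity_index",
    "daily_qoa",
    "wear_validity",
    "extract_daily_features",
    "day_features",
    "daily_features_to_frame",
]


@dataclass(frozen=True)
class EpochStat:
    """Mean and population SD of resultant acceleration in one epoch."""

    epoch_index: int
    mu: float
    sigma: float
    n_samples: int


@dataclass
class DailyFeatures:
    """All activity-based parameters of one patient-day.

    ``minute_ai`` is NaN for minutes with no recorded epoch;
    ``minute_coverage`` counts the recorded epochs (0–12) per minute.
    ``ri`` is NaN when undefined (first day, invalid neighbour, or a
    zero-variance hourly pattern).
    """

    patient_id: str
    date: dt.date
    minute_ai: np.ndarray  # (1440,) float64, NaN where unobserved
    minute_coverage: np.ndarray  # (1440,) int16
    hourly_pa: np.ndarray  # (24,) float64
    ri: float
    qoa: float
    wear_valid: bool
    wear_seconds: float
    #: set when rebuilt from a summary CSV without minute-level detail
    summary_override: dict | None = None

    @property
    def ai_values(self) -> np.ndarray:
        return self.minute_ai[~np.isnan(self.minute_ai)]

    def _stat(self, key: str, compute) -> float:
        if self.summary_override is not None:
            return float(self.summary_override[key])
        v = self.ai_values
        return compute(v) if v.size else 0.0

    @property
    def ai_sum(self) -> float:
        return self._stat("ai_sum", lambda v: float(v.sum()))

    @property
    def ai_mean(self) -> float:
        return self._stat("ai_mean", lambda v: float(v.mean()))

    @property
    def ai_median(self) -> float:
        return self._stat("ai_median", lambda v: float(np.median(v)))

    @property
    def ai_cov(self) -> float:
        """Coefficient of variation SD/mean of minute AI (0 if mean is 0)."""

        def _cov(v: np.ndarray) -> float:
            m = v.mean()
            return float(v.std() / m) if m > 0 else 0.0

        return self._stat("ai_cov", _cov)


def resultant_acceleration(ax, ay, az):
    """Euclidean norm of the three orthogonal acceleration components.

    Accepts scalars or arrays (element-wise); inputs in g-units.
    """
    ax = np.asarray(ax, dtype=np.float64)
    ay = np.asarray(ay, dtype=np.float64)
    az = np.asarray(az, dtype=np.float64)
    if not (np.all(np.isfinite(ax)) and np.all(np.isfinite(ay)) and np.all(np.isfinite(az))):
        raise ValueError("acceleration components must be finite")
    out = np.sqrt(ax * ax + ay * ay + az * az)
    return float(out) if out.ndim == 0 else out


def epoch_stats(
    samples: Sequence[float],
    epoch_index: int = 0,
    max_samples: int = 100,
) -> EpochStat:
    """Mean and population SD of resultant accelerations in one epoch.

    The SD uses the 1/N (population) form; it removes the constant
    gravity component so that ``σ_k`` quantifies actual movement. An
    empty epoch yields the missing marker (NaN statistics), never zero.
    """
    a = np.asarray(samples, dtype=np.float64)
    if a.size > max_samples:
        raise ValueError(f"epoch holds at most {max_samples} samples, got {a.size}")
    if a.size == 0:
        return EpochStat(epoch_index, math.nan, math.nan, 0)
    mu = float(a.mean())
    sigma = float(np.sqrt(np.mean((a - mu) ** 2)))
    return EpochStat(epoch_index, mu, sigma, int(a.size))


def minute_activity_index(
    epoch_sigmas: Sequence[float],
) -> tuple[float, int]:
    """Activity Index of one minute: sum of the 12 epoch SDs.

    Missing epochs (NaN) are excluded from the sum. Returns
    ``(ai, n_epochs_present)``; an all-missing minute yields
    ``(nan, 0)``.
    """
    s = np.asarray(epoch_sigmas, dtype=np.float64)
    if s.size > EPOCHS_PER_MINUTE:
        raise ValueError(
            f"a minute holds {EPOCHS_PER_MINUTE} epochs, got {s.size}"
        )
    present = ~np.isnan(s)
    n = int(present.sum())
    if n == 0:
        return math.nan, 0
    return float(s[present].sum()), n


def hourly_pa(minute_ai: Sequence[float]) -> float:
    """Hourly PA: sum of the minute-AI values of one clock hour.

    Missing minutes are excluded (sum over observed minutes only).
    """
    v = np.asarray(minute_ai, dtype=np.float64)
    present = ~np.isnan(v)
    return float(v[present].sum())


def regularity_index(
    hourly_prev: Sequence[float], hourly_curr: Sequence[float]
) -> float:
    """Pearson correlation of the 24-h hourly-PA patterns of consecutive days.

    Returns NaN (the undefined marker) if either pattern has zero
    variance — the correlation coefficient does not exist there.
    """
    a = np.asarray(hourly_prev, dtype=np.float64)
    b = np.asarray(hourly_curr, dtype=np.float64)
    if a.shape != (24,) or b.shape != (24,):
        raise ValueError("hourly-PA patterns must have 24 values")
    if np.isnan(a).any() or np.isnan(b).any():
        return math.nan
    sa = a.std()
    sb = b.std()
    if sa == 0.0 or sb == 0.0:
        return math.nan
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return min(1.0, max(-1.0, r))


def daily_qoa(minute_ai: Sequence[float], ri: float) -> float:
    """Quality of Activity: daily AI total scaled by (1 + RI).

    Blends activity volume with day-to-day regularity. An undefined RI
    (NaN) is substituted by 0 — regularity-neutral — so QoA degrades
    gracefully instead of becoming undefined.
    """
    total = hourly_pa(minute_ai)  # same missing-aware sum over any span
    r = 0.0 if (ri is None or math.isnan(ri)) else float(ri)
    return total * (1.0 + r)


def wear_validity(
    sample_index: np.ndarray,
    sampling_rate: float,
    max_gap_seconds: float | None = None,
) -> tuple[bool, float]:
    """Apply the ≥16 h/24 h wear rule to one calendar day of samples.

    ``wear_seconds`` is the cumulative recorded coverage (samples / fs).
    By default "continuous" is read cumulatively; if ``max_gap_seconds``
    is set, any single internal gap longer than it invalidates the day.
    """
    wear_seconds = float(len(sample_index)) / sampling_rate
    valid = wear_seconds >= WEAR_VALID_SECONDS
    if valid and max_gap_seconds is not None and len(sample_index) > 1:
        step = np.diff(sample_index)
        max_gap = (step.max() - 1) / sampling_rate
        if max_gap > max_gap_seconds:
            valid = False
    return valid, wear_seconds


def _epoch_sigma_day(
    sample_index: np.ndarray, resultant: np.ndarray, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch (σ_k, n_k) for one day, NaN where no samples.

    Two-pass (mean, then centred second moment) for numerical agreement
    with the direct formula down to machine precision.
    """
    spe = int(sampling_rate * EPOCH_SECONDS)
    if len(sample_index) == EPOCHS_PER_DAY * spe:
        # complete day: epoch blocks are contiguous, reshape directly
        r = resultant.reshape(EPOCHS_PER_DAY, spe)
        mu = r.mean(axis=1)
        centred = r - mu[:, None]
        sigma = np.sqrt(np.mean(centred * centred, axis=1))
        return sigma, np.full(EPOCHS_PER_DAY, float(spe))
    eid = sample_index // spe
    n = np.bincount(eid, minlength=EPOCHS_PER_DAY).astype(np.float64)
    s1 = np.bincount(eid, weights=resultant, minlength=EPOCHS_PER_DAY)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = s1 / n
    centred = resultant - mu[eid]
    s2 = np.bincount(eid, weights=centred * centred, minlength=EPOCHS_PER_DAY)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.sqrt(s2 / n)
    sigma[n == 0] = np.nan
    return sigma, n


def day_features(
    rec: DayRecord,
    patient_id: str,
    sampling_rate: float,
    prev: DailyFeatures | None = None,
    max_gap_seconds: float | None = None,
) -> DailyFeatures:
    """Compute all daily features for one calendar day of samples.

    ``prev`` must be the previous calendar day's features (or None); the
    Regularity Index chains consecutive wear-valid days only.
    """
    if len(rec.xyz):
        # float64 accumulation of ax²+ay²+az², identical to the scalar
        # resultant_acceleration applied element-wise
        res = np.sqrt(np.einsum("ij,ij->i", rec.xyz, rec.xyz, dtype=np.float64))
    else:
        res = np.empty(0, dtype=np.float64)

    sigma, n_per_epoch = _epoch_sigma_day(rec.sample_index, np.atleast_1d(res), sampling_rate) \
        if len(rec.sample_index) else (
            np.full(EPOCHS_PER_DAY, np.nan),
            np.zeros(EPOCHS_PER_DAY),
        )

    sig_m = sigma.reshape(MINUTES_PER_DAY, EPOCHS_PER_MINUTE)
    cover = (~np.isnan(sig_m)).sum(axis=1).astype(np.int16)
    with np.errstate(invalid="ignore"):
        minute_ai = np.nansum(sig_m, axis=1)
    minute_ai[cover == 0] = np.nan

    hp = np.nansum(
        np.nan_to_num(minute_ai.reshape(24, 60), nan=0.0), axis=1
    )

    valid, wear_seconds = wear_validity(
        rec.sample_index, sampling_rate, max_gap_seconds
    )

    ri = math.nan
    if valid and prev is not None and prev.wear_valid and (
        prev.date + dt.timedelta(days=1) == rec.date
    ):
        ri = regularity_index(prev.hourly_pa, hp)

    qoa = daily_qoa(minute_ai, ri)

    return DailyFeatures(
        patient_id=patient_id,
        date=rec.date,
        minute_ai=minute_ai,
        minute_coverage=cover,
        hourly_pa=hp,
        ri=ri,
        qoa=qoa,
        wear_valid=valid,
        wear_seconds=wear_seconds,
    )


def extract_daily_features(
    stream: AccelStream,
    max_gap_seconds: float | None = None,
) -> list[DailyFeatures]:
    """One :class:`DailyFeatures` per calendar day of a patient stream."""
    if np.any(np.diff(stream.sample_index) <= 0):
        raise ValueError("stream sample indices must be strictly increasing")
    out: list[DailyFeatures] = []
    prev: DailyFeatures | None = None
    for rec in stream.iter_days():
        feats = day_features(
            rec,
            stream.patient_id,
            stream.sampling_rate,
            prev=prev,
            max_gap_seconds=max_gap_seconds,
        )
        out.append(feats)
        prev = feats
    return out


def minute_ai_to_frame(daily: Sequence[DailyFeatures]) -> pd.DataFrame:
    """Long-format minute-level AI table (observed minutes only)."""
    rows = []
    for f in daily:
        present = np.nonzero(~np.isnan(f.minute_ai))[0]
        for m in present:
            rows.append(
                {
                    "patient_id": f.patient_id,
                    "date": f.date.isoformat(),
                    "minute": int(m) + 1,  # 1-based minute of day
                    "ai": float(f.minute_ai[m]),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "date", "minute", "ai"])


def daily_features_to_frame(daily: Sequence[DailyFeatures]) -> pd.DataFrame:
    """Daily summary table, one row per patient-day."""
    rows = [
        {
            "patient_id": f.patient_id,
            "date": f.date.isoformat(),
            "wear_valid": f.wear_valid,
            "wear_seconds": f.wear_seconds,
            "ai_sum": f.ai_sum,
            "ai_mean": f.ai_mean,
            "ai_median": f.ai_median,
            "ai_cov": f.ai_cov,
            "ri": f.ri,
            "qoa": f.qoa,
        }
        for f in daily
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "date",
            "wear_valid",
            "wear_seconds",
            "ai_sum",
            "ai_mean",
            "ai_median",
            "ai_cov",
            "ri",
            "qoa",
        ],
    )
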
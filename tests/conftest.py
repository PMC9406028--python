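"""Shared fixtures: hand-built daily features and small synthetic days."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from actipred.features import MINUTES_PER_DAY, DailyFeatures
from actipred.synth import DayRecord

D0 = dt.date(2016, 4, 1)


def make_day(
    patient_id: str = "P001",
    date: dt.date = D0,
    ai_per_minute: float = 0.5,
    ri: float = 0.2,
    wear_valid: bool = True,
) -> DailyFeatures:
    """A fabricated DailyFeatures record with a flat minute-AI profile."""
    minute_ai = np.full(MINUTES_PER_DAY, float(ai_per_minute))
    qoa = float(minute_ai.sum()) * (1.0 + (0.0 if np.isnan(ri) else ri))
    return DailyFeatures(
        patient_id=patient_id,
        date=date,
        minute_ai=minute_ai,
        minute_coverage=np.full(MINUTES_PER_DAY, 12, dtype=np.int16),
        hourly_pa=np.full(24, float(ai_per_minute) * 60.0),
        ri=float(ri),
        qoa=qoa,
        wear_valid=wear_valid,
        wear_seconds=86400.0,
    )


def make_days(
    n: int,
    patient_id: str = "P001",
    start: dt.date = D0,
    valid_mask=None,
    ai_values=None,
) -> list[DailyFeatures]:
    out = []
    for i in range(n):
        valid = True if valid_mask is None else bool(valid_mask[i])
        ai = 0.5 if ai_values is None else float(ai_values[i])
        out.append(
            make_day(
                patient_id,
                start + dt.timedelta(days=i),
                ai_per_minute=ai,
                wear_valid=valid,
            )
        )
    return out


def random_day_record(
    rng: np.random.Generator,
    sampling_rate: int = 5,
    n_hours: float = 24.0,
    gap_fraction: float = 0.0,
    date: dt.date = D0,
) -> DayRecord:
    """A random partial day of samples near 1 g for oracle checks."""
    n_full = int(sampling_rate * 3600 * n_hours)
    idx = np.arange(n_full, dtype=np.int64)
    if gap_fraction > 0:
        keep = rng.random(n_full) >= gap_fraction
        idx = idx[keep]
    xyz = (0.1 * rng.standard_normal((len(idx), 3))).astype(np.float32)
    xyz[:, 2] += 1.0
    return DayRecord(date=date, sample_index=idx, xyz=xyz)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2016)


def tiny_run_config(**kw):
    """A deliberately small cohort that still yields both classes."""
    from actipred.pipeline import RunConfig
    from actipred.synth import CohortConfig

    cohort = dict(
        n_patients=4,
        days_per_patient=60,
        sampling_rate=5,
        readmission_hazard=0.03,
        nonwear_rate=0.3,
        seed=5,
    )
    cohort.update(kw.pop("cohort", {}))
    base = dict(cohort=CohortConfig(**cohort), k_folds=4, n_epochs=40, seed=5)
    base.update(kw)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def tiny_result():
    from actipred.pipeline import run_all

    return run_all(tiny_run_config())
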
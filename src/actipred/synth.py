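"""Synthetic wearable-cohort generator.

Emulates the data a wrist-worn tri-axial accelerometer records from COPD
patients living at home: a gravity-dominated resting signal near 1 g,
circadian structure (quiet nights, bout-like daytime activity), non-wear
gaps, and — crucially for the prediction task — a progressive decline in
activity intensity over a configurable window preceding each simulated
hospital readmission.

The generator is the test bed for the whole pipeline: every downstream
stage (feature extraction, window labeling, model training, evaluation)
is exercised on cohorts produced here, with known ground truth.

A full patient at the default 20 Hz is ~4×10^8 samples, so the generator
exposes a per-day iterator (:func:`iter_patient_days`) that the pipeline
consumes without ever materializing a whole stream;
:func:`generate_patient` assembles an in-memory :class:`AccelStream` and
is intended for small cohorts and CSV export.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400
EPOCH_SECONDS = 5

__all__ = [
    "CohortConfig",
    "EventLog",
    "AccelStream",
    "DayRecord",
    "generate_patient",
    "generate_cohort",
    "iter_patient_days",
    "schedule_events",
]


class ConfigError(ValueError):
    """Raised for an invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated cohort.

    Defaults emulate the scale of a 16-patient COPD monitoring study
    (16 × 243 ≈ 3.9k patient-days) with a 10-day pre-readmission decline
    that halves bout intensity by the event day.

    Parameters
    ----------
    n_patients : number of patients in the cohort.
    days_per_patient : observation days per patient.
    sampling_rate : accelerometer sampling rate in samples/second. Must
        give an integer number of samples per 5 s epoch.
    night_activity_level : SD (g) of the resting jitter around gravity,
        present at all times (wrist tremor, posture shifts).
    day_activity_level : additional SD (g) contributed during an active
        daytime bout.
    bout_rate : expected active bouts per daytime hour (Poisson).
    bout_duration : bout duration in minutes.
    readmission_hazard : per-day probability of scheduling a readmission.
    decline_days : days over which pre-readmission activity attenuates.
    decline_floor : multiplicative bout attenuation reached on the event
        day (1 = no decline, 0 = total inactivity).
    nonwear_rate : expected non-wear gaps per day (Poisson).
    nonwear_duration : duration of each non-wear gap in hours.
    hospital_stay_days : days after a readmission with no recording
        (patient in hospital, device off).
    seed : master RNG seed; identical config ⇒ identical output bytes.
    """

    n_patients: int = 16
    days_per_patient: int = 243
    sampling_rate: int = 20
    night_activity_level: float = 0.02
    day_activity_level: float = 0.15
    bout_rate: float = 4.0
    bout_duration: float = 10.0
    readmission_hazard: float = 0.0055
    decline_days: int = 10
    decline_floor: float = 0.5
    nonwear_rate: float = 0.5
    nonwear_duration: float = 3.0
    hospital_stay_days: int = 5
    day_start_hour: int = 6
    day_end_hour: int = 23
    start_date: str = "2016-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "night_activity_level",
            "day_activity_level",
            "bout_rate",
            "bout_duration",
            "readmission_hazard",
            "nonwear_rate",
            "nonwear_duration",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.decline_floor <= 1.0:
            raise ConfigError("decline_floor must lie in [0, 1]")
        if not 0.0 <= self.readmission_hazard <= 1.0:
            raise ConfigError("readmission_hazard must lie in [0, 1]")
        if self.n_patients < 0 or self.days_per_patient < 0:
            raise ConfigError("counts must be >= 0")
        spe = self.sampling_rate * EPOCH_SECONDS
        if spe != int(spe) or spe < 1:
            raise ConfigError(
                "sampling_rate must yield an integer number of samples "
                f"per {EPOCH_SECONDS} s epoch (got {spe})"
            )

    @property
    def samples_per_epoch(self) -> int:
        return int(self.sampling_rate * EPOCH_SECONDS)

    @property
    def samples_per_day(self) -> int:
        return int(self.sampling_rate * SECONDS_PER_DAY)

    @property
    def start(self) -> dt.date:
        return dt.date.fromisoformat(self.start_date)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class EventLog:
    """Per-patient clinical record of hospital readmissions."""

    patient_id: str
    readmission_dates: list[dt.date]
    observation_start: dt.date
    observation_end: dt.date

    def __post_init__(self) -> None:
        dates = self.readmission_dates
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("readmission dates must be strictly increasing")
        for d in dates:
            if not self.observation_start <= d <= self.observation_end:
                raise ValueError(
                    f"readmission {d} outside observation window "
                    f"[{self.observation_start}, {self.observation_end}]"
                )


@dataclass
class DayRecord:
    """One calendar day of accelerometer samples from one patient.

    ``sample_index`` holds the day-local sample slots (0 .. fs·86400−1)
    that were actually recorded; non-wear spans are absent, not zeroed.
    """

    date: dt.date
    sample_index: np.ndarray  # int64, day-local, strictly increasing
    xyz: np.ndarray  # (n, 3) float32, g-units


@dataclass
class AccelStream:
    """A patient's tri-axial accelerometer record over consecutive days."""

    patient_id: str
    start_date: dt.date
    sampling_rate: float
    n_days: int
    sample_index: np.ndarray  # int64, global index since start 00:00
    xyz: np.ndarray  # (n, 3) float32

    def timestamps(self) -> pd.DatetimeIndex:
        t0 = pd.Timestamp(self.start_date)
        step_ns = int(round(1e9 / self.sampling_rate))
        return t0 + pd.to_timedelta(self.sample_index * step_ns, unit="ns")

    def iter_days(self) -> Iterator[DayRecord]:
        spd = int(self.sampling_rate * SECONDS_PER_DAY)
        day_of = self.sample_index // spd
        for d in range(self.n_days):
            sel = day_of == d
            yield DayRecord(
                date=self.start_date + dt.timedelta(days=d),
                sample_index=self.sample_index[sel] - d * spd,
                xyz=self.xyz[sel],
            )

    def to_csv(self, path: str | Path) -> None:
        """Write ``timestamp,ax,ay,az`` rows (ISO-8601, g-units)."""
        df = pd.DataFrame(
            {
                "timestamp": self.timestamps().strftime("%Y-%m-%dT%H:%M:%S.%f"),
                "ax": self.xyz[:, 0].astype(np.float64),
                "ay": self.xyz[:, 1].astype(np.float64),
                "az": self.xyz[:, 2].astype(np.float64),
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        patient_id: str,
        sampling_rate: float,
        start_date: dt.date | None = None,
        n_days: int | None = None,
    ) -> "AccelStream":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        ts = pd.DatetimeIndex(df["timestamp"])
        if not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly time-ordered")
        if start_date is None:
            start_date = ts[0].date()
        t0 = pd.Timestamp(start_date)
        offs_ns = (ts - t0).asi8
        step_ns = int(round(1e9 / sampling_rate))
        idx = np.round(offs_ns / step_ns).astype(np.int64)
        if n_days is None:
            n_days = int(idx[-1] // (sampling_rate * SECONDS_PER_DAY)) + 1
        xyz = df[["ax", "ay", "az"]].to_numpy(dtype=np.float32)
        return cls(patient_id, start_date, sampling_rate, n_days, idx, xyz)


def _derive_rng(config: CohortConfig, substream_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, substream_seed]))


def schedule_events(config: CohortConfig, rng: np.random.Generator) -> list[int]:
    """Draw readmission day-offsets for one patient.

    Day-by-day Bernoulli(`readmission_hazard`); the hazard is suspended
    during the in-hospital stay that follows each event.
    """
    events: list[int] = []
    day = 0
    while day < config.days_per_patient:
        if rng.random() < config.readmission_hazard:
            events.append(day)
            day += config.hospital_stay_days + 1
        else:
            day += 1
    return events


def _decline_factor(day: int, events: list[int], config: CohortConfig) -> float:
    """Multiplicative bout attenuation on ``day``.

    Ramps linearly from 1 at (event − decline_days) down to
    ``decline_floor`` on the event day; the minimum applies if windows of
    several events overlap.
    """
    factor = 1.0
    for e in events:
        if e - config.decline_days <= day <= e:
            if config.decline_days == 0:
                f = config.decline_floor
            else:
                frac = (e - day) / config.decline_days
                f = config.decline_floor + (1.0 - config.decline_floor) * frac
            factor = min(factor, f)
    return factor


def _hospital_days(events: list[int], config: CohortConfig) -> set[int]:
    out: set[int] = set()
    for e in events:
        out.update(range(e + 1, e + 1 + config.hospital_stay_days))
    return out


def _generate_day(
    config: CohortConfig,
    rng: np.random.Generator,
    decline: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One day of samples: (day-local sample index, (n,3) xyz in g)."""
    fs = config.sampling_rate
    n = config.samples_per_day

    # per-sample noise SD: resting jitter everywhere, bouts add on top
    sigma = np.full(n, config.night_activity_level, dtype=np.float32)
    active = np.zeros(n, dtype=bool)
    day_s0 = config.day_start_hour * 3600
    day_s1 = config.day_end_hour * 3600
    active_hours = (day_s1 - day_s0) / 3600.0
    if config.bout_rate > 0 and active_hours > 0:
        n_bouts = rng.poisson(config.bout_rate * active_hours)
        starts = rng.uniform(day_s0, day_s1, size=n_bouts)
        dur = config.bout_duration * 60.0
        for s in np.sort(starts):
            i0 = int(s * fs)
            i1 = min(int((s + dur) * fs), n)
            active[i0:i1] = True
    amp = np.float32(config.day_activity_level * decline)
    sigma[active] = np.sqrt(
        np.float32(config.night_activity_level) ** 2 + amp**2
    )

    xyz = rng.standard_normal((n, 3), dtype=np.float32)
    xyz *= sigma[:, None]
    xyz[:, 2] += 1.0  # gravity along the device z axis

    # non-wear gaps: flagged-missing spans (rows removed)
    n_gaps = rng.poisson(config.nonwear_rate) if config.nonwear_rate > 0 else 0
    gap_len = config.nonwear_duration * 3600.0
    gaps = []
    for _ in range(n_gaps):
        g0 = rng.uniform(0.0, SECONDS_PER_DAY)
        i0 = int(g0 * fs)
        i1 = min(int((g0 + gap_len) * fs), n)
        if i1 > i0:
            gaps.append((i0, i1))
    if not gaps:
        return np.arange(n, dtype=np.int64), xyz
    # merge overlapping gaps, then keep the complementary segments
    gaps.sort()
    merged = [list(gaps[0])]
    for i0, i1 in gaps[1:]:
        if i0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], i1)
        else:
            merged.append([i0, i1])
    segments = []
    cursor = 0
    for i0, i1 in merged:
        if i0 > cursor:
            segments.append((cursor, i0))
        cursor = i1
    if cursor < n:
        segments.append((cursor, n))
    idx = np.concatenate(
        [np.arange(a, b, dtype=np.int64) for a, b in segments]
    ) if segments else np.empty(0, dtype=np.int64)
    xyz = (
        np.concatenate([xyz[a:b] for a, b in segments])
        if segments
        else np.empty((0, 3), dtype=np.float32)
    )
    return idx, xyz


def iter_patient_days(
    config: CohortConfig,
    patient_id: str,
    substream_seed: int,
) -> tuple[EventLog, Iterator[DayRecord]]:
    """Event log plus a lazy per-day sample iterator for one patient.

    The iterator yields one :class:`DayRecord` per calendar day of the
    observation period; in-hospital days yield empty records.
    """
    rng = _derive_rng(config, substream_seed)
    event_days = schedule_events(config, rng)
    start = config.start
    end = start + dt.timedelta(days=max(config.days_per_patient - 1, 0))
    log = EventLog(
        patient_id=patient_id,
        readmission_dates=[start + dt.timedelta(days=e) for e in event_days],
        observation_start=start,
        observation_end=end,
    )
    hospital = _hospital_days(event_days, config)

    def _days() -> Iterator[DayRecord]:
        for d in range(config.days_per_patient):
            date = start + dt.timedelta(days=d)
            if d in hospital:
                yield DayRecord(
                    date=date,
                    sample_index=np.empty(0, dtype=np.int64),
                    xyz=np.empty((0, 3), dtype=np.float32),
                )
                continue
            decline = _decline_factor(d, event_days, config)
            idx, xyz = _generate_day(config, rng, decline)
            yield DayRecord(date=date, sample_index=idx, xyz=xyz)

    return log, _days()


def generate_patient(
    config: CohortConfig,
    patient_id: str,
    substream_seed: int,
) -> tuple[AccelStream, EventLog]:
    """Materialize one patient's full stream in memory.

    Suitable for small ``days_per_patient``; the pipeline uses
    :func:`iter_patient_days` for full-scale cohorts.
    """
    log, days = iter_patient_days(config, patient_id, substream_seed)
    spd = config.samples_per_day
    idx_parts: list[np.ndarray] = []
    xyz_parts: list[np.ndarray] = []
    for d, rec in enumerate(days):
        idx_parts.append(rec.sample_index + d * spd)
        xyz_parts.append(rec.xyz)
    if idx_parts:
        idx = np.concatenate(idx_parts)
        xyz = np.concatenate(xyz_parts)
    else:
        idx = np.empty(0, dtype=np.int64)
        xyz = np.empty((0, 3), dtype=np.float32)
    stream = AccelStream(
        patient_id=patient_id,
        start_date=config.start,
        sampling_rate=config.sampling_rate,
        n_days=config.days_per_patient,
        sample_index=idx,
        xyz=xyz,
    )
    return stream, log


def generate_cohort(config: CohortConfig) -> list[tuple[AccelStream, EventLog]]:
    """Deterministic fan-out of :func:`generate_patient` over the cohort."""
    return [
        generate_patient(config, f"P{i + 1:03d}", i)
        for i in range(config.n_patients)
    ]


def patient_ids(config: CohortConfig) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(config.n_patients)]


def write_event_log_csv(logs: list[EventLog], path: str | Path) -> None:
    rows = [
        {"patient_id": log.patient_id, "readmission_date": d.isoformat()}
        for log in logs
        for d in log.readmission_dates
    ]
    pd.DataFrame(rows, columns=["patient_id", "readmission_date"]).to_csv(
        path, index=False
    )


def read_event_log_csv(
    path: str | Path, manifest: dict[str, tuple[dt.date, dt.date]]
) -> dict[str, EventLog]:
    """Load event logs; ``manifest`` maps patient_id → (obs_start, obs_end)."""
    df = pd.read_csv(Path(path), dtype={"patient_id": str})
    logs: dict[str, EventLog] = {}
    for pid, (obs0, obs1) in manifest.items():
        sub = df[df["patient_id"] == pid]
        dates = sorted(
            dt.date.fromisoformat(str(d)) for d in sub["readmission_date"]
        )
        logs[pid] = EventLog(pid, dates, obs0, obs1)
    return logs


def write_manifest(
    config: CohortConfig, logs: list[EventLog], path: str | Path
) -> None:
    """Cohort manifest JSON: observation windows per patient + full config."""
    payload = {
        "config": config.to_dict(),
        "patients": {
            log.patient_id: {
                "observation_start": log.observation_start.isoformat(),
                "observation_end": log.observation_end.isoformat(),
                "n_readmissions": len(log.readmission_dates),
            }
            for log in logs
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> tuple[CohortConfig, dict[str, tuple[dt.date, dt.date]]]:
    payload = json.loads(Path(path).read_text())
    config = CohortConfig.from_dict(payload["config"])
    windows = {
        pid: (
            dt.date.fromisoformat(p["observation_start"]),
            dt.date.fromisoformat(p["observation_end"]),
        )
        for pid, p in payload["patients"].items()
    }
    return config, windows
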
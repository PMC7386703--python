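"""Shared domain types for the biologging pipeline.

All timestamps are timezone-aware UTC (the loggers are programmed in GMT and
peak times are reported in GMT; local display offsets are a presentation
concern). Downstream modules consume only these types — no module re-parses
files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from typing import Optional, Sequence

import numpy as np

HERDS = ("coastal", "inland")
GROUPS = ("juvenile_female", "juvenile_male", "adult_female")
SCHEDULES = ("base10min", "behav2min", "eval1min")

#: sampling interval (minutes) -> schedule tag of the logger programme
SCHEDULE_BY_INTERVAL = {10: "base10min", 2: "behav2min", 1: "eval1min"}


def _ensure_utc(t: datetime) -> datetime:
    if t.tzinfo is None:
        return t.replace(tzinfo=timezone.utc)
    return t.astimezone(timezone.utc)


@dataclass
class EcgWindow:
    """One raw single-channel ECG snippet (default 3 s at 200 Hz, microvolts).

    ``truth_beats`` (seconds from window start) is populated only by the
    synthetic generator and carries the ground-truth R-peak times.
    """

    animal_id: str
    start_time: datetime
    samples: np.ndarray
    sample_rate_hz: float = 200.0
    truth_beats: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.start_time = _ensure_utc(self.start_time)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must all be finite")
        if self.truth_beats is not None:
            self.truth_beats = np.asarray(self.truth_beats, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz


@dataclass(frozen=True)
class HrMeasurement:
    """A single logger heart-rate record: bpm plus the onboard quality grade.

    ``algo_quality`` is the logger's 0–3 reliability grade (0 best); quality
    below 2 is the accept threshold. ``hr_bpm`` may be NaN when the onboard
    algorithm could not compute a rate (always graded quality 3).
    """

    animal_id: str
    time: datetime
    hr_bpm: float
    algo_quality: int
    schedule_tag: str = "base10min"

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", _ensure_utc(self.time))
        if self.algo_quality not in (0, 1, 2, 3):
            raise ValueError(f"algo_quality must be 0–3, got {self.algo_quality!r}")
        if self.schedule_tag not in SCHEDULES:
            raise ValueError(f"unknown schedule_tag {self.schedule_tag!r}")
        if math.isnan(self.hr_bpm):
            if self.algo_quality != 3:
                raise ValueError("undefined HR must carry quality 3")
        elif not (0.0 < self.hr_bpm < 300.0) or not math.isfinite(self.hr_bpm):
            raise ValueError(f"hr_bpm out of physiologic range: {self.hr_bpm!r}")

    @property
    def hr_valid(self) -> bool:
        return not math.isnan(self.hr_bpm)


@dataclass(frozen=True)
class TbMeasurement:
    """A single core (abdominal) body-temperature record in °C."""

    animal_id: str
    time: datetime
    temp_c: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", _ensure_utc(self.time))
        if not (30.0 <= self.temp_c <= 45.0):
            raise ValueError(f"temp_c out of range [30, 45]: {self.temp_c!r}")


@dataclass
class AnimalRecord:
    """Metadata for one study animal (herd, demographic group, dates, weights)."""

    animal_id: str
    herd: str
    group: str
    birth_date: date
    implant_date: date
    end_date: date
    birth_weight_g: Optional[float] = None
    spring_weight_g: Optional[float] = None
    fall_weight_g: Optional[float] = None
    has_hr_sensor: bool = False
    has_tb_sensor: bool = False

    def __post_init__(self) -> None:
        if self.herd not in HERDS:
            raise ValueError(f"unknown herd {self.herd!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (self.birth_date <= self.implant_date < self.end_date):
            raise ValueError(
                f"{self.animal_id}: need birth_date <= implant_date < end_date, "
                f"got {self.birth_date} / {self.implant_date} / {self.end_date}"
            )
        for name in ("birth_weight_g", "spring_weight_g", "fall_weight_g"):
            w = getattr(self, name)
            if w is not None and w <= 0:
                raise ValueError(f"{self.animal_id}: {name} must be positive")


@dataclass
class Schedule:
    """A named logging schedule: sampling interval plus active time windows."""

    name: str
    interval_minutes: int
    active_windows: Sequence[tuple[datetime, datetime]] = field(default_factory=list)

    def __post_init__(self) -> None:
        wins = [(_ensure_utc(a), _ensure_utc(b)) for a, b in self.active_windows]
        for a, b in wins:
            if a >= b:
                raise ValueError("schedule window start must precede end")
        for (a0, b0), (a1, _b1) in zip(wins, wins[1:]):
            if a1 < b0:
                raise ValueError("schedule windows must be ordered and non-overlapping")
        self.active_windows = wins

    def covers(self, t: datetime) -> bool:
        t = _ensure_utc(t)
        return any(a <= t < b for a, b in self.active_windows)
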
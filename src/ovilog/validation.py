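"""Sensor-validation statistics.

The evaluation protocol plots each raw evaluation-burst ECG, grades it
visually into classes I (clean) to IV (noise makes interpretation
impossible), and compares that against the logger's own 0–3 grade. The key
error rates on the cross-tabulation:

* **false real** — the algorithm accepted (quality < 2) a strip that is
  visually class IV, i.e. it read a rate out of noise;
* **real false** — the algorithm rejected (quality 3, i.e. "above 2") a
  strip of visual class II or better, discarding a good measurement;
* **acceptance success** — among accepted strips, the share that is not
  class IV.

Agreement between the sensor rate and the manually measured rate is
summarized by the difference distribution and a zero-intercept least-squares
slope (intercepts forced through the origin). Activity-labelled means,
per-animal growth rates and a Welch comparison of sensor vs control growth
complete the surface.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import AnimalRecord, HrMeasurement
from .utils import round_half_up

MANUAL_CLASSES = ("I", "II", "III", "IV")
_CLASS_INDEX = {c: i for i, c in enumerate(MANUAL_CLASSES)}
_CLASS_INDEX.update({1: 0, 2: 1, 3: 2, 4: 3})


@dataclass
class QualityCrossTab:
    """4×4 counts: visual class I–IV (rows) × algorithm quality 0–3 (cols)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 4×4 matrix")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_accepted(self) -> int:
        """Measurements the logger accepts: algorithm quality < 2."""
        return int(self.counts[:, :2].sum())


def crosstab(pairs: Iterable[Tuple[object, int]]) -> QualityCrossTab:
    """Tally (manual_class, algo_quality) pairs; order-invariant."""
    counts = np.zeros((4, 4), dtype=int)
    for manual, algo in pairs:
        if manual not in _CLASS_INDEX:
            raise ValueError(f"unknown manual class {manual!r}")
        if algo not in (0, 1, 2, 3):
            raise ValueError(f"algo quality must be 0–3, got {algo!r}")
        counts[_CLASS_INDEX[manual], algo] += 1
    return QualityCrossTab(counts)


def false_real_rate(ct: QualityCrossTab) -> float:
    """% of all strips accepted (quality < 2) despite visual class IV."""
    if ct.n_total == 0:
        raise ValueError("empty cross-tabulation")
    return 100.0 * float(ct.counts[3, :2].sum()) / ct.n_total


def real_false_rate(ct: QualityCrossTab, algo_reading: str = "eq3") -> float:
    """% of all strips rejected despite visual class I or II.

    ``algo_reading='eq3'`` takes "quality above 2" literally (quality == 3);
    ``'ge2'`` widens rejection to quality ≥ 2. The narrow reading matches the
    published counts.
    """
    if ct.n_total == 0:
        raise ValueError("empty cross-tabulation")
    good = ct.counts[:2, :]
    if algo_reading == "eq3":
        n = good[:, 3].sum()
    elif algo_reading == "ge2":
        n = good[:, 2:].sum()
    else:
        raise ValueError(f"unknown algo_reading {algo_reading!r}")
    return 100.0 * float(n) / ct.n_total


def acceptance_success_rate(ct: QualityCrossTab) -> float:
    """% of accepted strips (quality 0&1) that are not visual class IV."""
    if ct.n_accepted == 0:
        raise ValueError("no accepted measurements")
    return 100.0 * (1.0 - float(ct.counts[3, :2].sum()) / ct.n_accepted)


def accepted_class_percentages(ct: QualityCrossTab, ndigits: int = 1) -> Dict[str, float]:
    """Per-class share of the accepted (quality < 2) strips, percent."""
    if ct.n_accepted == 0:
        raise ValueError("no accepted measurements")
    accepted = ct.counts[:, :2].sum(axis=1)
    return {
        c: round_half_up(100.0 * float(accepted[i]) / ct.n_accepted, ndigits)
        for i, c in enumerate(MANUAL_CLASSES)
    }


def manual_class_share(ct: QualityCrossTab, manual_class: str = "IV") -> float:
    """% of all strips with the given visual class (e.g. IV = uninterpretable)."""
    if ct.n_total == 0:
        raise ValueError("empty cross-tabulation")
    return 100.0 * float(ct.counts[_CLASS_INDEX[manual_class], :].sum()) / ct.n_total


def below_threshold_share(ct: QualityCrossTab) -> float:
    """% of all strips the logger accepts (algorithm quality < 2)."""
    if ct.n_total == 0:
        raise ValueError("empty cross-tabulation")
    return 100.0 * float(ct.n_accepted) / ct.n_total


def retrieval_rate(implanted: int, retrieved: int) -> float:
    """Sensor retrieval percentage, rounded to whole percent as tabulated."""
    if implanted <= 0 or retrieved < 0 or retrieved > implanted:
        raise ValueError("need 0 <= retrieved <= implanted, implanted > 0")
    return round_half_up(100.0 * retrieved / implanted, 0)


@dataclass
class AgreementStats:
    """Sensor-vs-manual HR agreement: difference moments and forced-origin slope."""

    mean_diff_bpm: float
    sd_diff: float
    min_diff: float
    max_diff: float
    slope_through_origin: float
    n_pairs: int


def agreement_stats(pairs: Sequence[Tuple[float, float]]) -> AgreementStats:
    """Differences sensor − manual, plus the zero-intercept LS slope
    Σ(sensor·manual)/Σ(manual²) of sensor on manual."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    arr = np.asarray(pairs, dtype=float)
    sensor, manual = arr[:, 0], arr[:, 1]
    diff = sensor - manual
    return AgreementStats(
        mean_diff_bpm=float(np.mean(diff)),
        sd_diff=float(np.std(diff, ddof=1)),
        min_diff=float(np.min(diff)),
        max_diff=float(np.max(diff)),
        slope_through_origin=float(np.sum(sensor * manual) / np.sum(manual**2)),
        n_pairs=len(pairs),
    )


def activity_means(
    measurements: Sequence[HrMeasurement],
    labels: Sequence[Tuple[object, object, str]],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Mean (SD, n) HR per demographic group × activity class.

    ``labels`` are observation intervals (start, end, label) with label in
    {"active", "passive"}; measurements outside every interval are dropped.
    """
    rows = []
    for m in measurements:
        for start, end, label in labels:
            s = pd.Timestamp(start).tz_localize("UTC") if pd.Timestamp(start).tzinfo is None else pd.Timestamp(start)
            e = pd.Timestamp(end).tz_localize("UTC") if pd.Timestamp(end).tzinfo is None else pd.Timestamp(end)
            if s <= pd.Timestamp(m.time) < e:
                rows.append((groups.get(m.animal_id, "all"), label, m.hr_bpm))
                break
    if not rows:
        raise ValueError("no measurement falls inside a labelled interval")
    df = pd.DataFrame(rows, columns=["group", "activity", "hr_bpm"])
    out = df.groupby(["group", "activity"])["hr_bpm"].agg(
        mean="mean", sd=lambda s: s.std(ddof=1), n="count"
    )
    return out


@dataclass
class GrowthRecord:
    """One lamb's growth summary for the sensor-vs-control comparison."""

    animal_id: str
    growth_g_per_day: float
    sensor_group: str  # "sensor" | "control"
    sex: Optional[str] = None
    rearing_rank: Optional[str] = None
    birth_day_of_year: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.growth_g_per_day):
            raise ValueError("growth must be finite")
        if self.sensor_group not in ("sensor", "control"):
            raise ValueError("sensor_group must be 'sensor' or 'control'")


def growth_rate(rec: AnimalRecord) -> float:
    """Gram/day from birth to the fall weighing (taken at end_date)."""
    if rec.birth_weight_g is None or rec.fall_weight_g is None:
        raise ValueError(f"{rec.animal_id}: need birth and fall weights")
    days = (rec.end_date - rec.birth_date).days
    if days <= 0:
        raise ValueError(f"{rec.animal_id}: non-positive growth interval")
    return (rec.fall_weight_g - rec.birth_weight_g) / days


def growth_comparison(
    records: Sequence[GrowthRecord], adjust_birth_day: bool = False
) -> dict:
    """Welch two-sample comparison of growth between sensor and control lambs.

    With ``adjust_birth_day`` the growth rates are first residualized on a
    straight-line fit against birth day of year (season-of-birth trend), and
    the test runs on the residuals; reported group means stay on the raw
    scale.
    """
    sensor = np.array([r.growth_g_per_day for r in records if r.sensor_group == "sensor"])
    control = np.array([r.growth_g_per_day for r in records if r.sensor_group == "control"])
    if len(sensor) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 lambs")
    x_s, x_c = sensor, control
    if adjust_birth_day:
        days = np.array([r.birth_day_of_year for r in records], dtype=float)
        if np.any(np.isnan(days)):
            raise ValueError("adjust_birth_day requires birth_day_of_year on every record")
        y = np.array([r.growth_g_per_day for r in records])
        slope, intercept = np.polyfit(days, y, 1)
        resid = y - (slope * days + intercept)
        grp = np.array([r.sensor_group for r in records])
        x_s, x_c = resid[grp == "sensor"], resid[grp == "control"]
    t_stat, p = stats.ttest_ind(x_s, x_c, equal_var=False)
    return {
        "mean_sensor": float(np.mean(sensor)),
        "mean_control": float(np.mean(control)),
        "mean_difference": float(np.mean(sensor) - np.mean(control)),
        "t": float(t_stat),
        "p_value": float(p),
        "n_sensor": int(len(sensor)),
        "n_control": int(len(control)),
    }
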
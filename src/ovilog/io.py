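"""Readers and writers for logger-export style CSV files and cohort metadata.

The commercial loggers export plain delimited text; dialects vary, so the
reader auto-detects the delimiter (semicolon or comma) from the header line
and accepts both dot- and comma-decimal numbers. Written files are canonical:
comma-delimited, dot-decimal, ISO 8601 UTC timestamps, sorted by time, so
``read(write(x))`` round-trips exactly.

Sensor CSV schema (invented here; the vendor format is not public):
``time,value[,quality[,schedule]]``. Metadata CSV columns mirror
:class:`~ovilog.types.AnimalRecord`. ECG CSV is long-format:
``animal_id,start_time,sample_rate_hz,sample_index,microvolts``.
"""
from __future__ import annotations

import math
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .types import AnimalRecord, EcgWindow, HrMeasurement, TbMeasurement

SensorRecord = Union[HrMeasurement, TbMeasurement]

_META_COLUMNS = [
    "animal_id", "herd", "group", "birth_date", "implant_date", "end_date",
    "birth_weight_g", "spring_weight_g", "fall_weight_g",
    "has_hr_sensor", "has_tb_sensor",
]


class CsvFormatError(ValueError):
    """Raised on malformed input, carrying the offending line number."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return ";" if ";" in header else ","


def _numeric(series: pd.Series, colname: str, first_data_line: int = 2) -> pd.Series:
    """Parse a string column accepting both '.' and ',' decimal separators.

    Uses exact (round-trip safe) float parsing, unlike pandas' fast parser.
    """
    cleaned = series.astype(str).str.strip().str.replace(",", ".", regex=False)
    cleaned = cleaned.replace({"": "nan", "None": "nan"})
    try:
        out = cleaned.to_numpy().astype(float)
    except ValueError:
        for i, raw in enumerate(cleaned):
            try:
                float(raw)
            except ValueError:
                raise CsvFormatError(
                    f"line {i + first_data_line}: cannot parse {colname} value {series.iloc[i]!r}"
                ) from None
        raise
    return pd.Series(out, index=series.index)


def _times(series: pd.Series, first_data_line: int = 2) -> pd.Series:
    out = pd.to_datetime(series, errors="coerce", utc=True, format="ISO8601")
    bad = out.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + first_data_line
        raise CsvFormatError(f"line {line}: cannot parse timestamp {series[bad].iloc[0]!r}")
    return out


def read_sensor_csv(path, kind: str) -> list[SensorRecord]:
    """Read a sensor export into HR or T_b records, sorted by time.

    Parameters
    ----------
    path : path-like
        Delimited text file with header ``time,value[,quality[,schedule]]``.
    kind : {"hr", "tb"}
        Which record type the file holds. T_b files have no quality channel.
    """
    path = Path(path)
    if kind not in ("hr", "tb"):
        raise ValueError(f"unknown sensor kind {kind!r}")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for required in ("time", "value"):
        if required not in df.columns:
            raise CsvFormatError(f"{path.name}: missing required column {required!r}")
    if df.empty:
        return []

    times = _times(df["time"])
    values = _numeric(df["value"], "value")
    animal = df["animal_id"].str.strip() if "animal_id" in df.columns else pd.Series(
        ["unknown"] * len(df)
    )

    records: list[SensorRecord] = []
    if kind == "hr":
        if "quality" not in df.columns:
            raise CsvFormatError(f"{path.name}: HR file requires a quality column")
        quality = _numeric(df["quality"], "quality")
        schedule = (
            df["schedule"].str.strip()
            if "schedule" in df.columns
            else pd.Series(["base10min"] * len(df))
        )
        for i in range(len(df)):
            q = quality.iloc[i]
            if q is None or math.isnan(q) or q != int(q) or int(q) not in (0, 1, 2, 3):
                raise CsvFormatError(f"line {i + 2}: quality must be an integer 0–3, got {df['quality'].iloc[i]!r}")
            try:
                records.append(
                    HrMeasurement(
                        animal_id=str(animal.iloc[i]),
                        time=times.iloc[i].to_pydatetime(),
                        hr_bpm=float(values.iloc[i]),
                        algo_quality=int(q),
                        schedule_tag=str(schedule.iloc[i]),
                    )
                )
            except ValueError as exc:
                raise CsvFormatError(f"line {i + 2}: {exc}") from exc
    else:
        for i in range(len(df)):
            try:
                records.append(
                    TbMeasurement(
                        animal_id=str(animal.iloc[i]),
                        time=times.iloc[i].to_pydatetime(),
                        temp_c=float(values.iloc[i]),
                    )
                )
            except ValueError as exc:
                raise CsvFormatError(f"line {i + 2}: {exc}") from exc
    records.sort(key=lambda r: (r.animal_id, r.time))
    return records


def write_sensor_csv(records: Sequence[SensorRecord], path) -> Path:
    """Write HR or T_b records as canonical comma/dot-decimal CSV, sorted."""
    path = Path(path)
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError("cannot mix HR and T_b records in one file")
    is_hr = not records or kinds == {HrMeasurement}
    rows = sorted(records, key=lambda r: (r.animal_id, r.time))
    with open(path, "w", encoding="utf-8") as fh:
        if is_hr:
            fh.write("animal_id,time,value,quality,schedule\n")
            for r in rows:
                v = "" if not r.hr_valid else repr(float(r.hr_bpm))
                fh.write(
                    f"{r.animal_id},{r.time.strftime('%Y-%m-%dT%H:%M:%S')},"
                    f"{v},{r.algo_quality},{r.schedule_tag}\n"
                )
        else:
            fh.write("animal_id,time,value\n")
            for r in rows:
                fh.write(
                    f"{r.animal_id},{r.time.strftime('%Y-%m-%dT%H:%M:%S')},"
                    f"{repr(float(r.temp_c))}\n"
                )
    return path


def _opt_float(raw: str) -> float | None:
    raw = raw.strip()
    if raw in ("", "NA", "nan", "None"):
        return None
    return float(raw.replace(",", "."))


def read_metadata(path) -> list[AnimalRecord]:
    """Read cohort metadata; missing weights are kept as absent, not errors."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _META_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise CsvFormatError(f"{path.name}: missing metadata columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                AnimalRecord(
                    animal_id=row["animal_id"].strip(),
                    herd=row["herd"].strip(),
                    group=row["group"].strip(),
                    birth_date=date.fromisoformat(row["birth_date"].strip()),
                    implant_date=date.fromisoformat(row["implant_date"].strip()),
                    end_date=date.fromisoformat(row["end_date"].strip()),
                    birth_weight_g=_opt_float(row.get("birth_weight_g", "")),
                    spring_weight_g=_opt_float(row.get("spring_weight_g", "")),
                    fall_weight_g=_opt_float(row.get("fall_weight_g", "")),
                    has_hr_sensor=row.get("has_hr_sensor", "0").strip() in ("1", "True", "true"),
                    has_tb_sensor=row.get("has_tb_sensor", "0").strip() in ("1", "True", "true"),
                )
            )
        except (ValueError, KeyError) as exc:
            raise CsvFormatError(f"line {i + 2}: {exc}") from exc
    return records


def write_metadata(records: Sequence[AnimalRecord], path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(_META_COLUMNS) + "\n")
        for r in records:
            fields = [
                r.animal_id, r.herd, r.group,
                r.birth_date.isoformat(), r.implant_date.isoformat(), r.end_date.isoformat(),
                "" if r.birth_weight_g is None else repr(float(r.birth_weight_g)),
                "" if r.spring_weight_g is None else repr(float(r.spring_weight_g)),
                "" if r.fall_weight_g is None else repr(float(r.fall_weight_g)),
                "1" if r.has_hr_sensor else "0",
                "1" if r.has_tb_sensor else "0",
            ]
            fh.write(",".join(fields) + "\n")
    return path


def write_ecg_csv(windows: Iterable[EcgWindow], path) -> Path:
    """Write ECG windows in long format (one row per sample)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("animal_id,start_time,sample_rate_hz,sample_index,microvolts\n")
        for w in windows:
            t0 = w.start_time.strftime("%Y-%m-%dT%H:%M:%S")
            for i, v in enumerate(w.samples):
                fh.write(f"{w.animal_id},{t0},{repr(float(w.sample_rate_hz))},{i},{repr(float(v))}\n")
    return path


def read_ecg_csv(path) -> list[EcgWindow]:
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if df.empty:
        return []
    df["start_time"] = _times(df["start_time"])
    df["sample_rate_hz"] = _numeric(df["sample_rate_hz"], "sample_rate_hz")
    df["sample_index"] = _numeric(df["sample_index"], "sample_index").astype(int)
    df["microvolts"] = _numeric(df["microvolts"], "microvolts")
    windows = []
    for (animal, t0, fs), grp in df.groupby(["animal_id", "start_time", "sample_rate_hz"], sort=True):
        grp = grp.sort_values("sample_index")
        windows.append(
            EcgWindow(
                animal_id=str(animal),
                start_time=t0.to_pydatetime(),
                samples=grp["microvolts"].to_numpy(),
                sample_rate_hz=float(fs),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# DataFrame conversion helpers used by the analysis modules

def hr_frame(records: Sequence[HrMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "time": pd.to_datetime([r.time for r in records], utc=True),
            "value": [r.hr_bpm for r in records],
            "quality": [r.algo_quality for r in records],
            "schedule": [r.schedule_tag for r in records],
        }
    )


def tb_frame(records: Sequence[TbMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "time": pd.to_datetime([r.time for r in records], utc=True),
            "value": [r.temp_c for r in records],
        }
    )
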
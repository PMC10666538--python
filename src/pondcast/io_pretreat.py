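"""Sensor/density log I/O, pretreatment and growth-interval assembly.

Pretreatment follows standard practice for pond sensor campaigns:

* seasonal sub-setting to the named experiment windows,
* Tukey box-plot outlier removal (values outside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``
  dropped) applied per pond / parameter stream,
* stride down-sampling to emulate instruments logging at a coarser cadence,
* growth intervals built from consecutive harvest-cycle density measurements;
  intervals that touch grow-out or final-harvest phases are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .productivity import areal_productivity
from .types import PARAMETERS, GrowthInterval, PondGeometry, SeasonWindow, SensorSeries

log = logging.getLogger(__name__)

#: Column names of the wide-form sensor log, in canonical parameter order.
WIDE_COLUMNS: dict[str, str] = {
    "ph": "pH",
    "temp_c": "T",
    "do_mgl": "DO",
    "tds_gl": "TDS",
    "par_uem2s": "PAR",
}

LONG_COLUMNS = ("timestamp", "pond_id", "parameter", "value")
DENSITY_COLUMNS = ("timestamp", "pond_id", "afdw_gl", "phase")


class SchemaError(ValueError):
    """A required column is missing or the file shape is not recognised."""


@dataclass
class ReadReport:
    """Row bookkeeping for a sensor-log read."""

    n_rows: int = 0
    n_malformed: int = 0
    malformed_lines: list[int] | None = None


def _series_from_frame(df: pd.DataFrame, cadence_minutes: int) -> dict[tuple[str, str], SensorSeries]:
    out: dict[tuple[str, str], SensorSeries] = {}
    for (pond, param), grp in df.groupby(["pond_id", "parameter"], sort=True):
        grp = grp.sort_values("timestamp")
        out[(str(pond), str(param))] = SensorSeries(
            pond_id=str(pond),
            parameter=str(param),
            times=pd.DatetimeIndex(grp["timestamp"]),
            values=grp["value"].to_numpy(dtype=float),
            cadence_minutes=cadence_minutes,
        )
    return out


def read_sensor_log(
    path,
    form: str = "auto",
    cadence_minutes: int = 15,
) -> tuple[dict[tuple[str, str], SensorSeries], ReadReport]:
    """Read a sensor log CSV into one :class:`SensorSeries` per (pond, parameter).

    Two schemas are accepted: long form ``timestamp,pond_id,parameter,value``
    and wide form ``timestamp,pond_id,ph,temp_c,do_mgl,tds_gl,par_uem2s``.
    Malformed rows (unparseable timestamp or value) are dropped, counted and
    reported with their line numbers.
    """
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if form == "auto":
        form = "long" if "parameter" in cols else "wide"

    report = ReadReport(n_rows=len(df), malformed_lines=[])
    if form == "long":
        missing = [c for c in LONG_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"sensor log missing columns {missing}")
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        val = pd.to_numeric(df["value"], errors="coerce")
        bad = ts.isna() | val.isna() | ~df["parameter"].isin(PARAMETERS)
        report.n_malformed = int(bad.sum())
        report.malformed_lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        tidy = pd.DataFrame(
            {"timestamp": ts[~bad], "pond_id": df.loc[~bad, "pond_id"],
             "parameter": df.loc[~bad, "parameter"], "value": val[~bad]}
        )
    elif form == "wide":
        required = ["timestamp", "pond_id", *WIDE_COLUMNS]
        missing = [c for c in required if c not in cols]
        if missing:
            raise SchemaError(f"sensor log missing columns {missing}")
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        frames = []
        bad_any = ts.isna().copy()
        for col, param in WIDE_COLUMNS.items():
            val = pd.to_numeric(df[col], errors="coerce")
            bad = ts.isna() | val.isna()
            bad_any |= val.isna()
            frames.append(
                pd.DataFrame(
                    {"timestamp": ts[~bad], "pond_id": df.loc[~bad, "pond_id"],
                     "parameter": param, "value": val[~bad]}
                )
            )
        report.n_malformed = int(bad_any.sum())
        report.malformed_lines = [int(i) + 2 for i in np.flatnonzero(bad_any.to_numpy())]
        tidy = pd.concat(frames, ignore_index=True)
    else:
        raise SchemaError(f"unknown sensor log form {form!r}")

    if report.n_malformed:
        log.warning("dropped %d malformed sensor rows (lines %s...)",
                    report.n_malformed, report.malformed_lines[:5])
    return _series_from_frame(tidy, cadence_minutes), report


def write_sensor_log(series: dict[tuple[str, str], SensorSeries] | list[SensorSeries], path) -> None:
    """Write series to the long-form CSV schema."""
    items = series.values() if isinstance(series, dict) else series
    frames = [
        pd.DataFrame(
            {"timestamp": s.times, "pond_id": s.pond_id, "parameter": s.parameter, "value": s.values}
        )
        for s in items
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_density_log(path) -> pd.DataFrame:
    """Read the density log CSV ``timestamp,pond_id,afdw_gl,phase``."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in DENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"density log missing columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["afdw_gl"] = pd.to_numeric(df["afdw_gl"])
    if (df["afdw_gl"] < 0).any():
        raise ValueError("AFDW values must be non-negative")
    return df.sort_values(["pond_id", "timestamp"]).reset_index(drop=True)


class DegenerateSeriesError(ValueError):
    """Pretreatment removed every record of a series."""


def remove_outliers(series: SensorSeries) -> SensorSeries:
    """Drop values outside the Tukey box-plot whiskers.

    Whiskers are ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` with linearly interpolated
    quartiles (numpy's default, R type 7).  Order is preserved.
    """
    q1, q3 = np.percentile(series.values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (series.values >= lo) & (series.values <= hi)
    if not mask.any():
        raise DegenerateSeriesError(
            f"outlier removal emptied series {series.pond_id}/{series.parameter}"
        )
    if mask.all():
        return series
    return SensorSeries(
        pond_id=series.pond_id,
        parameter=series.parameter,
        times=series.times[mask],
        values=series.values[mask],
        cadence_minutes=series.cadence_minutes,
    )


def select_season(obj, window: SeasonWindow):
    """Restrict a SensorSeries or density DataFrame to a seasonal window.

    Timestamps within ``[start_date, end_date]`` (whole-day inclusive on the
    end date) are retained.  Empty results are allowed: for a series, ``None``
    is returned; for a frame, an empty frame.
    """
    end = pd.Timestamp(window.end_date) + pd.Timedelta(days=1)
    if isinstance(obj, SensorSeries):
        mask = (obj.times >= window.start_date) & (obj.times < end)
        if not mask.any():
            return None
        return SensorSeries(
            pond_id=obj.pond_id, parameter=obj.parameter,
            times=obj.times[mask], values=obj.values[mask],
            cadence_minutes=obj.cadence_minutes,
        )
    df = obj
    mask = (df["timestamp"] >= pd.Timestamp(window.start_date)) & (df["timestamp"] < end)
    return df.loc[mask].reset_index(drop=True)


def downsample(series: SensorSeries, target_minutes: int) -> SensorSeries:
    """Keep every (target/cadence)-th record starting from the first.

    Emulates an instrument logging less often; no averaging is performed.
    """
    if target_minutes % series.cadence_minutes != 0:
        raise ValueError(
            f"target cadence {target_minutes} is not a multiple of {series.cadence_minutes}"
        )
    stride = target_minutes // series.cadence_minutes
    if stride == 1:
        return series
    return SensorSeries(
        pond_id=series.pond_id,
        parameter=series.parameter,
        times=series.times[::stride],
        values=series.values[::stride],
        cadence_minutes=target_minutes,
    )


def assemble_intervals(
    densities: pd.DataFrame,
    sensor_series: dict[tuple[str, str], SensorSeries],
    geometry: PondGeometry = PondGeometry(),
    max_missing_frac: float = 0.10,
) -> list[GrowthInterval]:
    """Build labeled growth intervals from consecutive harvest-cycle densities.

    Consecutive density measurements both tagged ``harvest_cycle`` delimit an
    interval; pairs touching ``grow_out`` or ``final_harvest`` rows are
    excluded, as are intervals missing any of the five parameter streams or
    with more than ``max_missing_frac`` of expected sensor records absent.
    Sensor windows are half-open ``[start, end)`` so the boundary record is
    never double counted.
    """
    intervals: list[GrowthInterval] = []
    for pond, grp in densities.groupby("pond_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        for i in range(len(grp) - 1):
            a, b = grp.iloc[i], grp.iloc[i + 1]
            if a["phase"] != "harvest_cycle" or b["phase"] != "harvest_cycle":
                continue
            start, end = a["timestamp"], b["timestamp"]
            duration = (end - start).total_seconds() / 86400.0
            windows: dict[str, SensorSeries] = {}
            ok = True
            for param in PARAMETERS:
                s = sensor_series.get((str(pond), param))
                w = s.clipped(start, end) if s is not None else None
                if w is None:
                    warnings.warn(
                        f"interval {pond} {start}: missing stream {param}; excluded",
                        stacklevel=2,
                    )
                    ok = False
                    break
                expected = duration * 1440.0 / w.cadence_minutes
                if len(w) < (1.0 - max_missing_frac) * expected:
                    warnings.warn(
                        f"interval {pond} {start}: {param} has too many gaps; excluded",
                        stacklevel=2,
                    )
                    ok = False
                    break
                windows[param] = w
            if not ok:
                continue
            intervals.append(
                GrowthInterval(
                    pond_id=str(pond),
                    start=start.to_pydatetime(),
                    end=end.to_pydatetime(),
                    duration_days=duration,
                    afdw_start=float(a["afdw_gl"]),
                    afdw_end=float(b["afdw_gl"]),
                    productivity=areal_productivity(
                        float(a["afdw_gl"]), float(b["afdw_gl"]), duration, geometry
                    ),
                    sensor_windows=windows,
                )
            )
    return intervals


def interval_table(intervals: list[GrowthInterval]) -> pd.DataFrame:
    """Tabular summary in the interval-table CSV schema."""
    return pd.DataFrame(
        {
            "pond_id": [iv.pond_id for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "duration_d": [iv.duration_days for iv in intervals],
            "afdw_start": [iv.afdw_start for iv in intervals],
            "afdw_end": [iv.afdw_end for iv in intervals],
            "productivity_gm2d": [iv.productivity for iv in intervals],
        }
    )
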
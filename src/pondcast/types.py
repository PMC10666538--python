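"""Core domain containers shared across the package.

The data model mirrors the field workflow for open raceway pond (ORP)
cultivation: continuously logged water-chemistry / light sensors (pH,
temperature, dissolved oxygen, total dissolved solids, photosynthetically
active radiation) and sparse manual ash-free dry weight (AFDW) density
measurements that bracket harvest-to-harvest growth intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

#: Canonical parameter order used everywhere (panels, feature columns, configs).
PARAMETERS: tuple[str, ...] = ("pH", "T", "DO", "TDS", "PAR")

#: Units per parameter, for documentation and plot sidecars.
PARAMETER_UNITS: dict[str, str] = {
    "pH": "-",
    "T": "degC",
    "DO": "mg/L",
    "TDS": "g/L",
    "PAR": "uE/m2/s",
}

#: Density-log phase tags.
PHASES: tuple[str, ...] = ("grow_out", "harvest_cycle", "final_harvest")


@dataclass
class SensorSeries:
    """One parameter's timestamped values for one pond at a stated cadence.

    Timestamps are naive local time.  Gaps (missing cadence steps) are
    permitted; consumers that care call :meth:`gap_fraction`.
    """

    pond_id: str
    parameter: str
    times: pd.DatetimeIndex
    values: np.ndarray
    cadence_minutes: int

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}; expected one of {PARAMETERS}")
        if self.cadence_minutes <= 0:
            raise ValueError("cadence_minutes must be positive")
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if len(self.times) == 0:
            raise ValueError("SensorSeries must hold at least one record")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sensor values must be finite")
        dt = np.diff(self.times.asi8)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def gap_fraction(self) -> float:
        """Fraction of expected cadence slots in [first, last] that are missing."""
        if len(self) < 2:
            return 0.0
        span_min = (self.times[-1] - self.times[0]).total_seconds() / 60.0
        expected = int(round(span_min / self.cadence_minutes)) + 1
        return max(0.0, 1.0 - len(self) / expected)

    def clipped(self, start: datetime, end: datetime) -> "SensorSeries | None":
        """Records with start <= t < end (half-open window), or None if empty."""
        mask = (self.times >= start) & (self.times < end)
        if not mask.any():
            return None
        return SensorSeries(
            pond_id=self.pond_id,
            parameter=self.parameter,
            times=self.times[mask],
            values=self.values[mask],
            cadence_minutes=self.cadence_minutes,
        )


@dataclass(frozen=True)
class PondGeometry:
    """ORP geometry used to convert volumetric AFDW change to areal productivity."""

    volume_l: float = 1025.0
    area_m2: float = 4.2

    def __post_init__(self) -> None:
        if self.volume_l <= 0 or self.area_m2 <= 0:
            raise ValueError("pond volume and area must be positive")


@dataclass(frozen=True)
class SeasonWindow:
    """Named seasonal experiment window (inclusive dates)."""

    name: str
    start_date: datetime
    end_date: datetime

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("end_date must be >= start_date")


#: The four seasonal experiment windows of the 2014-2015 field campaign.
SEASONS: tuple[SeasonWindow, ...] = (
    SeasonWindow("spring14", datetime(2014, 4, 18), datetime(2014, 5, 28)),
    SeasonWindow("summer14", datetime(2014, 6, 23), datetime(2014, 7, 25)),
    SeasonWindow("fall14", datetime(2014, 9, 22), datetime(2014, 10, 24)),
    SeasonWindow("winter14", datetime(2014, 12, 29), datetime(2015, 1, 23)),
)


@dataclass
class GrowthInterval:
    """One labeled sample: a harvest-to-harvest window with its sensor windows.

    ``productivity`` is areal (g/m2/d), derived from the AFDW endpoints via the
    pond geometry; it may be negative (net biomass loss) and is stored as-is.
    """

    pond_id: str
    start: datetime
    end: datetime
    duration_days: float
    afdw_start: float
    afdw_end: float
    productivity: float
    sensor_windows: dict[str, SensorSeries] = field(default_factory=dict)

    @property
    def interval_id(self) -> str:
        return f"{self.pond_id}:{pd.Timestamp(self.start).isoformat()}"

    def __post_init__(self) -> None:
        if pd.Timestamp(self.end) <= pd.Timestamp(self.start):
            raise ValueError("interval end must be after start")
        if self.duration_days <= 0:
            raise ValueError("duration_days must be positive")


@dataclass(frozen=True)
class RegressionMetrics:
    """(R^2, RMSE, MAE) triple used for all model evaluation."""

    r2: float
    rmse: float
    mae: float

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae}
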
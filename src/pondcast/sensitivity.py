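"""Sensitivity procedures: resolution sweeps, log fit, perturbation index.

Three probes of the image-based model (IBM):

1. **Monitoring-resolution sweep** — retrain the IBM after stride-downsampling
   the sensor streams (e.g. 15, 60, 240 min) and fit test R^2 against
   ln(resolution) by ordinary least squares.
2. **Image-resolution sweep** — retrain at image sizes 224/336/448.
3. **Per-parameter perturbation sensitivity** — re-encode selected intervals
   with graded shrink manipulations of one parameter at a time, accumulate the
   absolute prediction change over the factor grid, and normalize by the most
   sensitive parameter so that it scores an index of exactly 1.0.

Percent-change arithmetic uses the reference value as denominator throughout:
an *improvement* is the signed relative gain of the new value in the metric's
better direction, and a *penalty* is its negation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging import FACTOR_GRID, PerturbationSpec, ProfileImageEncoder
from .models import ProfileImageRegressor, SplitSpec, train_ibm
from .types import PARAMETERS, GrowthInterval, RegressionMetrics


@dataclass(frozen=True)
class SweepResult:
    """Metrics of one sweep point (a monitoring cadence or an image size)."""

    axis_value: float
    train: RegressionMetrics
    test: RegressionMetrics


@dataclass(frozen=True)
class LogFit:
    """OLS fit of test R^2 on ln(resolution minutes)."""

    slope: float
    intercept: float
    fit_r2: float

    def predict(self, minutes) -> np.ndarray:
        return self.slope * np.log(np.asarray(minutes, dtype=float)) + self.intercept


@dataclass
class SensitivityResult:
    """Per-parameter cumulative perturbation errors and normalized indices."""

    cumulative_error: dict[str, float]
    cumulative_percent_error: dict[str, float]
    index: dict[str, float] | None
    per_interval: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    @property
    def most_sensitive(self) -> str | None:
        if self.index is None:
            return None
        return max(self.index, key=self.index.get)


def percent_change(reference: float, new: float, lower_is_better: bool = False,
                   direction: str = "improvement") -> float:
    """Relative change in percent, reference-denominator convention.

    ``improvement`` is positive when ``new`` is better than ``reference`` in
    the metric's stated orientation; ``penalty`` is the sign-flipped
    counterpart.
    """
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    if direction not in ("improvement", "penalty"):
        raise ValueError("direction must be 'improvement' or 'penalty'")
    imp = (reference - new) / reference if lower_is_better else (new - reference) / reference
    pct = 100.0 * imp
    return -pct if direction == "penalty" else pct


def fit_log_curve(points: list[tuple[float, float]]) -> LogFit:
    """OLS of test R^2 on ln(minutes) over ``(minutes, r2)`` points."""
    if len(points) < 2:
        raise ValueError("need at least two points")
    x = np.log(np.array([p[0] for p in points], dtype=float))
    y = np.array([p[1] for p in points], dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("minutes must be positive")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_tot = float(((y - y.mean()) ** 2).sum())
    fit_r2 = 1.0 if ss_tot == 0 else 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot
    return LogFit(slope=float(slope), intercept=float(intercept), fit_r2=fit_r2)


def resolution_sweep(
    intervals: list[GrowthInterval],
    labels: np.ndarray,
    split: SplitSpec,
    resolutions: tuple[int, ...] = (15, 60, 240),
    size: int = 224,
    seed: int = 0,
    **ibm_params,
) -> list[SweepResult]:
    """Train one IBM per monitoring resolution with the shared split.

    Training failures at one resolution are recorded (NaN metrics) without
    aborting the rest of the sweep.
    """
    out = []
    for mins in sorted(set(resolutions)):
        try:
            enc = ProfileImageEncoder(
                size=size, resolution_minutes=None if _is_base(intervals, mins) else mins
            )
            images = enc.transform(intervals)
            _, m_train, m_test = train_ibm(images, labels, split, seed=seed, **ibm_params)
        except Exception as exc:  # propagate per-point without aborting the sweep
            warnings.warn(f"resolution {mins} failed: {exc}", stacklevel=2)
            nan = RegressionMetrics(float("nan"), float("nan"), float("nan"))
            m_train = m_test = nan
        out.append(SweepResult(axis_value=float(mins), train=m_train, test=m_test))
    return out


def _is_base(intervals: list[GrowthInterval], mins: int) -> bool:
    cadence = next(iter(intervals[0].sensor_windows.values())).cadence_minutes
    return mins == cadence


def image_resolution_sweep(
    intervals: list[GrowthInterval],
    labels: np.ndarray,
    split: SplitSpec,
    sizes: tuple[int, ...] = (224, 336, 448),
    seed: int = 0,
    **ibm_params,
) -> list[SweepResult]:
    """Train one IBM per image size with the shared split."""
    out = []
    for size in sorted(set(sizes)):
        try:
            images = ProfileImageEncoder(size=size).transform(intervals)
            _, m_train, m_test = train_ibm(images, labels, split, seed=seed, **ibm_params)
        except Exception as exc:
            warnings.warn(f"image size {size} failed: {exc}", stacklevel=2)
            nan = RegressionMetrics(float("nan"), float("nan"), float("nan"))
            m_train = m_test = nan
        out.append(SweepResult(axis_value=float(size * size), train=m_train, test=m_test))
    return out


def select_best_predicted(
    intervals: list[GrowthInterval],
    predictions: np.ndarray,
    hrt_days: tuple[int, ...] = (2, 3, 7),
) -> list[GrowthInterval]:
    """The best-predicted interval for each hydraulic retention time.

    For each requested HRT, returns the interval of that duration whose
    prediction is closest to its label.
    """
    labels = np.array([iv.productivity for iv in intervals])
    err = np.abs(predictions - labels)
    chosen = []
    for hrt in hrt_days:
        idx = [i for i, iv in enumerate(intervals) if round(iv.duration_days) == hrt]
        if not idx:
            warnings.warn(f"no interval with HRT {hrt} d", stacklevel=2)
            continue
        chosen.append(intervals[idx[int(np.argmin(err[idx]))]])
    return chosen


def parameter_sensitivity(
    model: ProfileImageRegressor,
    intervals: list[GrowthInterval],
    factor_grid: tuple[float, ...] = FACTOR_GRID,
    perturb_kind: str = "shrink",
    size: int = 224,
) -> SensitivityResult:
    """Cumulative prediction change under graded per-parameter perturbations.

    For every parameter and manipulation factor the targeted panel is
    re-encoded with the perturbation (magnitude perturbations keep the
    unperturbed axis extent as a floor), the ensemble re-predicts, and the
    absolute and percent deviations from the unperturbed prediction accumulate
    over the grid and over the supplied intervals.  Indices normalize by the
    most sensitive parameter; ties are all reported at 1.0 with a warning.
    """
    base_images = ProfileImageEncoder(size=size).transform(intervals)
    base_pred = model.predict(base_images)

    cum_abs = {p: 0.0 for p in PARAMETERS}
    cum_pct = {p: 0.0 for p in PARAMETERS}
    per_interval: dict[str, dict[str, list[float]]] = {
        p: {iv.interval_id: [] for iv in intervals} for p in PARAMETERS
    }
    for param in PARAMETERS:
        for f in factor_grid:
            spec = PerturbationSpec(kind=perturb_kind, factor=float(f), parameter=param)
            images = ProfileImageEncoder(size=size, perturbation=spec).transform(intervals)
            pred = model.predict(images)
            diff = np.abs(pred - base_pred)
            cum_abs[param] += float(diff.sum())
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = np.where(base_pred != 0, 100.0 * diff / np.abs(base_pred), np.nan)
            cum_pct[param] += float(np.nansum(pct))
            for iv, d in zip(intervals, diff):
                per_interval[param][iv.interval_id].append(float(d))

    max_err = max(cum_abs.values())
    if max_err == 0.0:
        warnings.warn("all cumulative errors are zero; sensitivity index undefined",
                      stacklevel=2)
        index = None
    else:
        index = {p: cum_abs[p] / max_err for p in PARAMETERS}
        winners = [p for p, v in index.items() if v == 1.0]
        if len(winners) > 1:
            warnings.warn(f"sensitivity tie between {winners}; all reported at 1.0",
                          stacklevel=2)
    return SensitivityResult(
        cumulative_error=cum_abs,
        cumulative_percent_error=cum_pct,
        index=index,
        per_interval=per_interval,
    )
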
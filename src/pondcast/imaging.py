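"""Profile-plot image encoding of growth intervals, and perturbation operators.

Each growth interval is encoded as a square RGB raster built by splicing five
horizontal panels, one per sensor parameter in the fixed order
(pH, T, DO, TDS, PAR).  A panel is a bare line plot of value versus time:
no axes, ticks, labels or margins, a 1-pixel solid line on a white
background.  The y-axis autoscales to the data range padded by 5%, so the
encoding is invariant to a vertical offset of the whole trace — only the
shape of the trend is represented.  Rasterization uses integer Bresenham
segments with no anti-aliasing, so identical inputs yield identical bytes.

Perturbation operators act on a series ``X`` with window mean ``Xbar``:

* ``offset``:  ``A = X + s * F * Xbar``   (position shift, trend preserved)
* ``expand``:  ``B = Xbar + (1 + F) * (X - Xbar)``  (deviations amplified)
* ``shrink``:  ``C = Xbar + (X - Xbar) / (1 + F)``  (deviations attenuated)

When a perturbed panel is rendered for sensitivity analysis, magnitude
perturbations reuse the unperturbed series' axis extent as a floor: the axis
expands to fit larger data but never contracts.  Consequently an expansion is
invisible (the axis grows with the data and the drawn shape is unchanged)
while a shrink leaves the axis at its original span and visibly flattens the
line — the asymmetry that makes only the shrink operator informative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

from .types import PARAMETERS, GrowthInterval, SensorSeries

#: Panel foreground colors (RGB), one per parameter, fixed for model reuse.
PANEL_COLORS: dict[str, tuple[int, int, int]] = {
    "pH": (31, 119, 180),
    "T": (214, 39, 40),
    "DO": (44, 160, 44),
    "TDS": (148, 103, 189),
    "PAR": (255, 127, 14),
}

BACKGROUND = (255, 255, 255)

VALID_SIZES = (224, 336, 448)

#: Default manipulation-factor grid for sensitivity analysis.
FACTOR_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 21) * 0.05, 2))


@dataclass(frozen=True)
class PerturbationSpec:
    """One synthetic manipulation of one parameter's series."""

    kind: str  # offset | expand | shrink
    factor: float
    parameter: str
    sign: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("offset", "expand", "shrink"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.factor < 0:
            raise ValueError("factor must be >= 0")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")


def perturb(series: SensorSeries, spec: PerturbationSpec) -> SensorSeries:
    """Apply a perturbation operator to a series (mean taken over the window)."""
    x = series.values
    xbar = float(np.mean(x))
    if spec.kind == "offset":
        new = x + spec.sign * spec.factor * xbar
    elif spec.kind == "expand":
        new = xbar + (1.0 + spec.factor) * (x - xbar)
    else:  # shrink
        new = xbar + (x - xbar) / (1.0 + spec.factor)
    return SensorSeries(
        pond_id=series.pond_id,
        parameter=series.parameter,
        times=series.times,
        values=new,
        cadence_minutes=series.cadence_minutes,
    )


def padded_extent(values: np.ndarray, pad_frac: float = 0.05) -> tuple[float, float]:
    """Data range padded symmetrically by ``pad_frac`` of the range."""
    lo, hi = float(np.min(values)), float(np.max(values))
    pad = pad_frac * (hi - lo)
    return lo - pad, hi + pad


def _draw_segment(mask: np.ndarray, c0: int, r0: int, c1: int, r1: int) -> None:
    """Integer Bresenham line on a boolean mask (rows, cols)."""
    dc, dr = abs(c1 - c0), abs(r1 - r0)
    sc = 1 if c1 >= c0 else -1
    sr = 1 if r1 >= r0 else -1
    if dc >= dr:
        err = dc // 2
        r = r0
        for c in range(c0, c1 + sc, sc):
            mask[r, c] = True
            err -= dr
            if err < 0:
                r += sr
                err += dc
    else:
        err = dr // 2
        c = c0
        for r in range(r0, r1 + sr, sr):
            mask[r, c] = True
            err -= dc
            if err < 0:
                c += sc
                err += dr


def render_panel(
    series: SensorSeries,
    width: int,
    height: int,
    axis_limits: tuple[float, float] | None = None,
    time_range: tuple | None = None,
    pad_frac: float = 0.05,
    gap_break_steps: float = 1.5,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rasterize one parameter trace into a boolean line mask.

    Returns ``(mask, (axis_lo, axis_hi))`` where ``mask[r, c]`` is True on the
    line.  The y-axis spans the 5%-padded data range, expanded (never
    contracted) to cover ``axis_limits`` when given.  A constant series with
    no axis information draws a horizontal line at band mid-height.  Gaps
    longer than ``gap_break_steps`` cadence steps break the line.
    """
    if width <= 0 or height <= 0:
        raise ValueError("band dimensions must be positive")
    v = series.values
    lo, hi = padded_extent(v, pad_frac)
    if axis_limits is not None:
        lo = min(lo, float(axis_limits[0]))
        hi = max(hi, float(axis_limits[1]))

    t = series.times.asi8.astype(np.float64)
    if time_range is not None:
        t0 = pd.Timestamp(time_range[0]).value
        t1 = pd.Timestamp(time_range[1]).value
    else:
        t0, t1 = t[0], t[-1]
    span = t1 - t0
    if span <= 0:
        cols = np.zeros(len(v), dtype=np.int64)
    else:
        cols = np.floor((t - t0) / span * (width - 1) + 0.5).astype(np.int64)
    cols = np.clip(cols, 0, width - 1)

    if hi > lo:
        u = (v - lo) / (hi - lo)
        # Quantize before pixel mapping so that exactly-equivalent traces
        # (e.g. offset by a constant) rasterize to identical rows despite
        # last-ulp float drift.
        u = np.round(u, 9)
        rows = (height - 1) - np.floor(u * (height - 1) + 0.5).astype(np.int64)
    else:
        rows = np.full(len(v), (height - 1) // 2, dtype=np.int64)
    rows = np.clip(rows, 0, height - 1)

    mask = np.zeros((height, width), dtype=bool)
    gap_ns = gap_break_steps * series.cadence_minutes * 60e9
    mask[rows[0], cols[0]] = True
    for i in range(len(v) - 1):
        if t[i + 1] - t[i] > gap_ns:
            mask[rows[i + 1], cols[i + 1]] = True  # discontinuity
            continue
        _draw_segment(mask, int(cols[i]), int(rows[i]), int(cols[i + 1]), int(rows[i + 1]))
    return mask, (lo, hi)


@dataclass
class ProfileImage:
    """Fixed-size spliced raster encoding of one growth interval."""

    pixels: np.ndarray  # (H, W, 3) uint8
    interval_id: str
    layout: list[dict] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0] * self.pixels.shape[1]

    def save(self, path, sidecar: bool = True) -> None:
        Image.fromarray(self.pixels).save(path, format="PNG")
        if sidecar:
            meta = {"interval_id": self.interval_id, "layout": self.layout}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ProfileImage":
        pixels = np.asarray(Image.open(path).convert("RGB"))
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"interval_id": "", "layout": []}
        return cls(pixels=pixels, interval_id=meta["interval_id"], layout=meta["layout"])


def band_heights(size: int) -> list[int]:
    """Panel heights for a square of side ``size``: floor(size/5) each, remainder to the last."""
    h = size // 5
    return [h, h, h, h, size - 4 * h]


def render_interval_image(
    interval: GrowthInterval,
    size: int = 224,
    perturbation: PerturbationSpec | None = None,
    pad_frac: float = 0.05,
) -> ProfileImage:
    """Encode a growth interval as a spliced five-panel profile image.

    Panels are stacked vertically in the order pH, T, DO, TDS, PAR.  With a
    magnitude perturbation (expand/shrink), the targeted panel is rendered
    with the unperturbed series' padded extent as its axis floor; offset
    perturbations render under plain autoscale, which is what makes them
    invisible to the encoding.
    """
    if size not in VALID_SIZES:
        raise ValueError(f"size must be one of {VALID_SIZES}")
    heights = band_heights(size)
    pixels = np.empty((size, size, 3), dtype=np.uint8)
    pixels[:] = BACKGROUND
    layout: list[dict] = []
    row0 = 0
    for param, h in zip(PARAMETERS, heights):
        series = interval.sensor_windows.get(param)
        if series is None:
            raise ValueError(f"interval {interval.interval_id} missing parameter {param}")
        axis_limits = None
        if perturbation is not None and perturbation.parameter == param:
            if perturbation.kind in ("expand", "shrink"):
                axis_limits = padded_extent(series.values, pad_frac)
            series = perturb(series, perturbation)
        mask, limits = render_panel(
            series,
            width=size,
            height=h,
            axis_limits=axis_limits,
            time_range=(interval.start, interval.end),
            pad_frac=pad_frac,
        )
        pixels[row0 : row0 + h][mask] = PANEL_COLORS[param]
        layout.append(
            {
                "parameter": param,
                "row0": row0,
                "row1": row0 + h,
                "axis_lo": limits[0],
                "axis_hi": limits[1],
                "color": PANEL_COLORS[param],
            }
        )
        row0 += h
    return ProfileImage(pixels=pixels, interval_id=interval.interval_id, layout=layout)


def images_to_model_input(images: list[ProfileImage], pool: int = 4) -> np.ndarray:
    """Stack images into a float32 (N, 1, H/pool, W/pool) tensor in [0, 1].

    Images are converted to a grayscale ink mask (1 where any line pixel,
    0 background) and mean-pooled by ``pool`` to the CNN's working size.
    """
    arrs = []
    for im in images:
        ink = (im.pixels != 255).any(axis=2).astype(np.float32)
        h, w = ink.shape
        ink = ink[: h - h % pool, : w - w % pool]
        ink = ink.reshape(h // pool, pool, w // pool, pool).mean(axis=(1, 3))
        arrs.append(ink[None])
    return np.stack(arrs).astype(np.float32)


class ProfileImageEncoder(BaseEstimator, TransformerMixin):
    """Transformer from growth intervals to profile images.

    Parameters
    ----------
    size : int
        Image side length; one of 224, 336, 448.
    resolution_minutes : int or None
        If set, sensor windows are stride-downsampled to this cadence first.
    perturbation : PerturbationSpec or None
        Optional manipulation applied to one parameter before rendering.
    pad_frac : float
        Fractional y-axis padding applied to every autoscaled panel.
    """

    def __init__(
        self,
        size: int = 224,
        resolution_minutes: int | None = None,
        perturbation: PerturbationSpec | None = None,
        pad_frac: float = 0.05,
    ):
        self.size = size
        self.resolution_minutes = resolution_minutes
        self.perturbation = perturbation
        self.pad_frac = pad_frac

    def fit(self, X, y=None):  # noqa: D102 - stateless
        return self

    def transform(self, X: list[GrowthInterval]) -> list[ProfileImage]:
        from .io_pretreat import downsample

        out = []
        for interval in X:
            if self.resolution_minutes is not None:
                windows = {
                    p: downsample(s, self.resolution_minutes)
                    for p, s in interval.sensor_windows.items()
                }
                interval = GrowthInterval(
                    pond_id=interval.pond_id,
                    start=interval.start,
                    end=interval.end,
                    duration_days=interval.duration_days,
                    afdw_start=interval.afdw_start,
                    afdw_end=interval.afdw_end,
                    productivity=interval.productivity,
                    sensor_windows=windows,
                )
            out.append(
                render_interval_image(
                    interval, size=self.size, perturbation=self.perturbation, pad_frac=self.pad_frac
                )
            )
        return out
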
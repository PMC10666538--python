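"""Seeded synthetic raceway-pond sensor and density streams.

The generator emulates the statistical structure of an outdoor pond
monitoring campaign — diurnal light, temperature tracking light with a lag,
photosynthesis-driven dissolved-oxygen and pH swings, slowly drifting total
dissolved solids, and sparse density measurements every 2-7 days — with a
known ground-truth productivity rule, so the whole image-encoding/model
pipeline can be exercised and verified without any external download.

Ground-truth rule
-----------------
Daily volumetric growth (g/L/d) of pond ``p`` on day ``d`` is

    g(p, d) = mu_max * M_d / (M_d + K_L) * exp(-lambda * f_d)

where ``M_d`` is the day's mean PAR (a saturating Monod light term) and
``f_d`` is the fraction of the day with water temperature above the stress
threshold ``T_crit``.  AFDW accumulates daily growth; interval productivity
is the areal conversion of the AFDW change, so stored truth equals the
assembled label exactly.

Temperature is generated as baseline + amplitude * lagged diurnal shape +
noise, passed through a soft cap (softmin at ``t_cap``) that emulates
evaporative cooling: ponds whose raw temperature would exceed the cap show
flat-topped traces.  Because the image encoding is invariant to affine
rescaling of a panel, this capping is what makes heat-stress excursions
*visible* in the image: two ponds can share an interval-mean temperature
(identical tabular features) while their traces - and their labels - differ.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .productivity import areal_productivity
from .types import PARAMETERS, PondGeometry, SensorSeries

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class ParamEnvelope:
    """Per-parameter generation envelope: target mean, diurnal swing, noise."""

    mean: float
    amplitude: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic campaign.

    Envelope defaults approximate the Georgia testbed summary statistics
    (pH 8.0, DO 6.8 mg/L, TDS 27.0 g/L, PAR mean 377.7 uE/m2/s); the
    temperature scenario is a warm season in which diurnal amplitude, not
    mean, controls time above the stress threshold.
    """

    n_ponds: int = 12
    n_days: int = 58
    cadence_minutes: int = 15
    harvest_interval_days: tuple[int, ...] = (2, 3, 4, 7)
    start: datetime = datetime(2014, 6, 1)
    afdw0: float = 0.35
    seed: int = 0

    ph: ParamEnvelope = ParamEnvelope(8.0, 0.35, 0.05)
    temperature: ParamEnvelope = ParamEnvelope(26.0, 8.0, 0.4)
    do: ParamEnvelope = ParamEnvelope(6.8, 5.0, 0.4)
    tds: ParamEnvelope = ParamEnvelope(27.0, 0.0, 0.05)
    par: ParamEnvelope = ParamEnvelope(377.7, 0.0, 0.35)  # noise_sd = daily cloud log-sd

    #: half-range of the per-pond uniform draw around temperature.amplitude
    t_amp_spread: float = 4.0
    t_lag_minutes: int = 120
    t_cap: float | None = 33.0
    t_cap_softness: float = 1.5
    t_daily_sd: float = 0.8  # day-to-day baseline weather shift
    par_intraday_sd: float = 0.08  # log-sd of within-day PAR flicker

    # ground-truth productivity rule
    mu_max: float = 0.04  # g/L/d at light saturation, no stress
    k_light: float = 60.0  # Monod half-saturation on daily-mean PAR
    lam: float = 3.0  # stress penalty rate
    t_crit: float = 29.5  # stress threshold (degC)

    geometry: PondGeometry = PondGeometry()

    def __post_init__(self) -> None:
        if MINUTES_PER_DAY % self.cadence_minutes != 0:
            raise ValueError("cadence must divide 1440")
        if self.n_days < max(self.harvest_interval_days, default=1):
            raise ValueError("n_days must cover at least one harvest interval")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), default=str, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class SynthPond:
    """One generated pond: five sensor streams, density log and truth labels."""

    pond_id: str
    series: dict[str, SensorSeries]
    densities: pd.DataFrame
    truth: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _diurnal_shape(hours: np.ndarray) -> np.ndarray:
    """Solar half-sine: sin(pi*(h-6)/12) for h in [6, 18], zero at night."""
    s = np.sin(np.pi * (hours - 6.0) / 12.0)
    return np.where((hours >= 6.0) & (hours <= 18.0), np.maximum(s, 0.0), 0.0)


def _rng(seed: int, pond_idx: int, stream: int) -> np.random.Generator:
    # Counter-based child seeds: adding ponds or streams never perturbs others.
    return np.random.default_rng(np.random.SeedSequence((seed, pond_idx, stream)))


def _soft_cap(x: np.ndarray, cap: float | None, w: float) -> np.ndarray:
    if cap is None:
        return x
    # softmin(x, cap): smooth saturation emulating evaporative cooling
    return -w * np.logaddexp(-x / w, -cap / w)


def generate_pond(
    config: SynthConfig,
    pond_idx: int = 0,
    harvest_interval_days: int | None = None,
    t_amplitude: float | None = None,
) -> SynthPond:
    """Generate one pond's streams, density log and per-interval truth."""
    steps_per_day = MINUTES_PER_DAY // config.cadence_minutes
    n_steps = config.n_days * steps_per_day
    hrt = harvest_interval_days or config.harvest_interval_days[
        pond_idx % len(config.harvest_interval_days)
    ]

    times = pd.date_range(
        config.start, periods=n_steps, freq=f"{config.cadence_minutes}min"
    )
    hours = (times - times[0]).total_seconds().to_numpy() / 3600.0 % 24.0
    day_idx = np.arange(n_steps) // steps_per_day

    s = _diurnal_shape(hours)
    s_lag = _diurnal_shape((hours - config.t_lag_minutes / 60.0) % 24.0)
    s_mean = float(s.mean())
    s_lag_mean = float(s_lag.mean())

    pond_rng = _rng(config.seed, pond_idx, 98)
    weather_rng = _rng(config.seed, pond_idx, 99)

    if t_amplitude is None:
        t_amplitude = config.temperature.amplitude + pond_rng.uniform(
            -config.t_amp_spread, config.t_amp_spread
        )
    pond_t_jitter = pond_rng.normal(0.0, 0.3)

    cloud = np.exp(
        weather_rng.normal(
            -0.5 * config.par.noise_sd**2, config.par.noise_sd, size=config.n_days
        )
    )
    t_shift = weather_rng.normal(0.0, config.t_daily_sd, size=config.n_days)

    # PAR: clear-sky half-sine scaled to the target mean, daily cloud factor,
    # small within-day multiplicative flicker; exactly zero at night.
    par_rng = _rng(config.seed, pond_idx, PARAMETERS.index("PAR"))
    peak = config.par.mean / s_mean if s_mean > 0 else 0.0
    flicker = np.exp(
        par_rng.normal(-0.5 * config.par_intraday_sd**2, config.par_intraday_sd, n_steps)
    )
    par = peak * s * cloud[day_idx] * flicker
    par[s == 0.0] = 0.0

    # Temperature: baseline chosen so the interval mean sits at the envelope
    # mean regardless of amplitude, then soft-capped.
    t_rng = _rng(config.seed, pond_idx, PARAMETERS.index("T"))
    t_base = config.temperature.mean - t_amplitude * s_lag_mean + pond_t_jitter
    t_raw = (
        t_base
        + t_amplitude * s_lag
        + t_shift[day_idx]
        + t_rng.normal(0.0, config.temperature.noise_sd, n_steps)
    )
    temp = _soft_cap(t_raw, config.t_cap, config.t_cap_softness)

    # DO and pH ride the (cloud-modulated) light signal in deviation form.
    do_rng = _rng(config.seed, pond_idx, PARAMETERS.index("DO"))
    light_norm = s * cloud[day_idx]
    do = (
        config.do.mean
        + config.do.amplitude * (light_norm - light_norm.mean())
        + do_rng.normal(0.0, config.do.noise_sd, n_steps)
    )
    ph_rng = _rng(config.seed, pond_idx, PARAMETERS.index("pH"))
    ph = (
        config.ph.mean
        + config.ph.amplitude * (light_norm - light_norm.mean())
        + ph_rng.normal(0.0, config.ph.noise_sd, n_steps)
    )

    # TDS: bounded random walk around its mean.
    tds_rng = _rng(config.seed, pond_idx, PARAMETERS.index("TDS"))
    steps = tds_rng.normal(0.0, config.tds.noise_sd, n_steps)
    tds = np.empty(n_steps)
    level = config.tds.mean
    for i in range(n_steps):  # bounded walk needs the running clip
        level = np.clip(level + steps[i], config.tds.mean - 3.0, config.tds.mean + 3.0)
        tds[i] = level

    values = {"pH": ph, "T": temp, "DO": do, "TDS": tds, "PAR": par}
    pond_id = f"P{pond_idx:02d}"
    series = {
        p: SensorSeries(pond_id, p, times, values[p], config.cadence_minutes)
        for p in PARAMETERS
    }

    # Ground-truth rule and AFDW accumulation.
    daily_mean_par = np.array(
        [par[day_idx == d].mean() for d in range(config.n_days)]
    )
    f_stress = np.array(
        [(temp[day_idx == d] > config.t_crit).mean() for d in range(config.n_days)]
    )
    growth = (
        config.mu_max
        * daily_mean_par
        / (daily_mean_par + config.k_light)
        * np.exp(-config.lam * f_stress)
    )
    afdw_daily = config.afdw0 + np.concatenate([[0.0], np.cumsum(growth)])

    meas_days = list(range(0, config.n_days + 1, hrt))
    rows = []
    for k, d in enumerate(meas_days):
        rows.append(
            {
                "timestamp": config.start + timedelta(days=d),
                "pond_id": pond_id,
                "afdw_gl": afdw_daily[d],
                "phase": "grow_out" if k == 0 else "harvest_cycle",
            }
        )
    densities = pd.DataFrame(rows)

    truth_rows = []
    for d0, d1 in zip(meas_days[1:-1], meas_days[2:]):
        truth_rows.append(
            {
                "pond_id": pond_id,
                "start": config.start + timedelta(days=d0),
                "end": config.start + timedelta(days=d1),
                "true_productivity_gm2d": areal_productivity(
                    afdw_daily[d0], afdw_daily[d1], d1 - d0, config.geometry
                ),
            }
        )
    truth = pd.DataFrame(truth_rows)

    return SynthPond(
        pond_id=pond_id,
        series=series,
        densities=densities,
        truth=truth,
        metadata={
            "seed": config.seed,
            "pond_idx": pond_idx,
            "config_hash": config.content_hash(),
            "hrt_days": hrt,
            "t_amplitude": float(t_amplitude),
        },
    )


@dataclass
class SynthDataset:
    """A collection of generated ponds with merged views and CSV export."""

    ponds: list[SynthPond]
    config: SynthConfig

    def sensor_series(self) -> dict[tuple[str, str], SensorSeries]:
        return {(p.pond_id, param): s for p in self.ponds for param, s in p.series.items()}

    def densities(self) -> pd.DataFrame:
        if not self.ponds:
            return pd.DataFrame(columns=["timestamp", "pond_id", "afdw_gl", "phase"])
        return pd.concat([p.densities for p in self.ponds], ignore_index=True)

    def truth(self) -> pd.DataFrame:
        if not self.ponds:
            return pd.DataFrame(columns=["pond_id", "start", "end", "true_productivity_gm2d"])
        return pd.concat([p.truth for p in self.ponds], ignore_index=True)

    def to_csv(self, out_dir) -> None:
        from .io_pretreat import write_sensor_log

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sensor_log(self.sensor_series(), out / "sensors.csv")
        self.densities().to_csv(out / "densities.csv", index=False)
        self.truth().to_csv(out / "truth.csv", index=False)
        with open(out / "config.txt", "w") as fh:
            for key, val in asdict(self.config).items():
                fh.write(f"{key}={val}\n")


def generate_dataset(config: SynthConfig, n_ponds: int | None = None) -> SynthDataset:
    """Generate ``n_ponds`` ponds with per-pond child seeds (counter-derived)."""
    n = config.n_ponds if n_ponds is None else n_ponds
    return SynthDataset(
        ponds=[generate_pond(config, pond_idx=i) for i in range(n)], config=config
    )


def generate_matched_pair(
    config: SynthConfig | None = None,
    amp_lo: float = 4.0,
    amp_hi: float = 12.0,
    hrt_days: int = 7,
    seed: int = 0,
) -> tuple[SynthPond, SynthPond]:
    """Two ponds with equal interval-mean temperature but different heat stress.

    Noise, clouds and flicker are disabled and both ponds reuse the same child
    seeds, so pH/DO/TDS/PAR streams are identical.  The low-amplitude pond
    stays below the stress threshold; the high-amplitude pond's temperature is
    soft-capped (flat-topped trace) and its envelope mean is re-solved by root
    finding so both capped traces share the same time-mean.  Tabular features
    of the pair are therefore equal while the profile images and the
    ground-truth labels differ - the structure an averaging model cannot see.
    """
    base = config or SynthConfig()
    quiet = replace(
        base,
        seed=seed,
        n_days=hrt_days * 2,
        harvest_interval_days=(hrt_days,),
        ph=replace(base.ph, noise_sd=0.0),
        temperature=replace(base.temperature, noise_sd=0.0),
        do=replace(base.do, noise_sd=0.0),
        tds=replace(base.tds, noise_sd=0.0),
        par=replace(base.par, noise_sd=0.0),
        par_intraday_sd=0.0,
        t_daily_sd=0.0,
        t_amp_spread=0.0,
    )
    pond_lo = generate_pond(quiet, pond_idx=0, t_amplitude=amp_lo)
    target_mean = float(pond_lo.series["T"].values.mean())

    # Solve the envelope mean for the high-amplitude pond so that its capped
    # trace has the same time-mean as the low-amplitude pond.
    def mean_gap(env_mean: float) -> float:
        cfg = replace(quiet, temperature=replace(quiet.temperature, mean=env_mean))
        p = generate_pond(cfg, pond_idx=0, t_amplitude=amp_hi)
        return float(p.series["T"].values.mean()) - target_mean

    # bracket the sign change (the cap depresses the mean, so the matching
    # envelope mean lies above the target; scan defensively either way)
    lo_b, hi_b = target_mean - 2.0, target_mean + 8.0
    grid = np.linspace(lo_b, hi_b, 21)
    vals = [mean_gap(g) for g in grid]
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va == 0.0 or va * vb < 0:
            lo_b, hi_b = a, b
            break
    env_mean = brentq(mean_gap, lo_b, hi_b, xtol=1e-10)
    cfg_hi = replace(quiet, temperature=replace(quiet.temperature, mean=env_mean))
    pond_hi = generate_pond(cfg_hi, pond_idx=0, t_amplitude=amp_hi)
    pond_hi.pond_id = "P00b"
    pond_hi.densities["pond_id"] = "P00b"
    pond_hi.truth["pond_id"] = "P00b"
    for s in pond_hi.series.values():
        s.pond_id = "P00b"
    return pond_lo, pond_hi


def excursion_scenario(seed: int, n_ponds: int = 12, n_days: int = 58) -> SynthConfig:
    """The default heat-excursion study scenario (~200 labeled intervals)."""
    return SynthConfig(n_ponds=n_ponds, n_days=n_days, seed=seed)
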
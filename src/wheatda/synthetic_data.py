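"""Synthetic weather, twin-experiment observations and regional grids.

Emulates the data environment of a semi-humid North China Plain winter
wheat season: a dry winter with spring irrigation events, wet summers,
sparse satellite-cadence LAI and soil-moisture observations (7 LAI dates
and 8 SM dates between late February and late May) with multiplicative
Gaussian noise of 10% (LAI) and 35% (SM), and a regional grid of cells
with varying wheat fraction. Every generator is a pure function of its
specification and seed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .crop_model import (CropParams, CropState, SeasonResult, SoilParams,
                         WeatherDay, run_season)

__all__ = [
    "ClimateSpec",
    "ObservationPlan",
    "ObservationRecord",
    "RegionalGridSpec",
    "RegionalCell",
    "angstrom_radiation",
    "daylength",
    "extraterrestrial_radiation",
    "generate_weather",
    "generate_twin",
    "sample_observations",
    "generate_region",
    "default_climate",
    "default_observation_plan",
]

_SOLAR_CONSTANT = 0.0820  # MJ m^-2 min^-1 (FAO-56)


@dataclass(frozen=True)
class ObservationRecord:
    """A dated LAI or SM measurement with its relative error magnitude."""

    date: dt.date
    variable: str  # "LAI" | "SM"
    value: float
    rel_error: float

    def __post_init__(self):
        if self.variable not in ("LAI", "SM"):
            raise ValueError("variable must be 'LAI' or 'SM'")
        if self.value < 0:
            raise ValueError("observed values must be non-negative")
        if self.variable == "SM" and self.value >= 1:
            raise ValueError("volumetric soil moisture must be < 1")
        if self.rel_error < 0:
            raise ValueError("relative error must be non-negative")


@dataclass(frozen=True)
class ClimateSpec:
    """Statistical description of the synthetic daily weather process.

    Temperature is a seasonal sinusoid (annual mean, amplitude, coldest
    day-of-year) plus iid Gaussian noise, with a fixed diurnal range.
    Rainfall occurrence is a first-order two-state (wet/dry) chain with
    monthly stationary wet-day probability and exponential wet-day depths;
    this matches the dry-winter/wet-summer seasonality without claiming to
    be a calibrated climatology. Sunshine fractions are Beta-distributed,
    lower on wet days, and converted to radiation through the Angstrom
    formula. Irrigation events are inserted verbatim.
    """

    latitude: float = 37.7
    t_mean: float = 12.5  # degC annual mean
    t_amplitude: float = 14.5  # degC seasonal half-range
    t_phase_doy: int = 15  # coldest day of year
    t_noise_sd: float = 2.0
    diurnal_range: float = 10.0
    wet_prob_by_month: tuple[float, ...] = (
        0.05, 0.06, 0.12, 0.15, 0.18, 0.30, 0.40, 0.38, 0.28, 0.15, 0.07, 0.05)
    wet_depth_by_month: tuple[float, ...] = (
        1.5, 2.0, 4.0, 6.0, 8.0, 11.0, 14.0, 13.0, 9.0, 7.0, 3.0, 1.5)
    wet_persistence_boost: float = 0.3  # p(wet|wet) = p + boost (capped)
    irrigation_events: tuple[tuple[dt.date, float], ...] = ()
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50
    sunshine_beta_dry: tuple[float, float] = (4.0, 1.8)
    sunshine_beta_wet: tuple[float, float] = (1.5, 4.0)

    def __post_init__(self):
        if len(self.wet_prob_by_month) != 12 or len(self.wet_depth_by_month) != 12:
            raise ValueError("monthly rain tables need 12 entries")
        if any(not 0 <= p <= 1 for p in self.wet_prob_by_month):
            raise ValueError("wet-day probabilities must lie in [0, 1]")
        if self.angstrom_a <= 0 or self.angstrom_b <= 0:
            raise ValueError("Angstrom coefficients must be positive")
        if self.angstrom_a + self.angstrom_b > 1:
            raise ValueError("Angstrom a + b must not exceed 1")

    @property
    def mean_annual_rainfall_mm(self) -> float:
        days = (31, 28.25, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
        return float(sum(d * p * m for d, p, m in
                         zip(days, self.wet_prob_by_month,
                             self.wet_depth_by_month)))


@dataclass(frozen=True)
class ObservationPlan:
    """Sparse observation calendar with per-variable relative errors."""

    lai_dates: tuple[dt.date, ...]
    sm_dates: tuple[dt.date, ...]
    rel_errors: Mapping[str, float] = field(
        default_factory=lambda: {"LAI": 0.10, "SM": 0.35})
    sm_bias: float = 0.0  # additive cm^3 cm^-3, emulating sensing-depth bias

    def __post_init__(self):
        if any(e < 0 for e in self.rel_errors.values()):
            raise ValueError("relative errors must be non-negative")


@dataclass(frozen=True)
class RegionalGridSpec:
    """Synthetic regional grid of 1 km-style cells.

    ``param_jitter_sd`` is the relative sd of the per-cell *truth*
    parameter jitter (applied to the six perturbation targets) used to
    synthesise each cell's observations; the assimilating model itself is
    run with the same base parameters everywhere.
    """

    n_rows: int = 20
    n_cols: int = 20
    threshold: float = 0.40
    param_jitter_sd: float = 0.10
    wheat_fraction_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        lo, hi = self.wheat_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("wheat fractions must lie in [0, 1]")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")


@dataclass(frozen=True)
class RegionalCell:
    row: int
    col: int
    wheat_fraction: float
    truth_crop: CropParams
    truth_soil: SoilParams
    truth_yield: float
    observations: tuple[ObservationRecord, ...]


# ---------------------------------------------------------------------------
# FAO-56 solar geometry and the Angstrom formula


def _solar_geometry(latitude: float, doy: int) -> tuple[float, float]:
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (24.0 * 60.0 / math.pi) * _SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws))
    return ra, ws


def extraterrestrial_radiation(latitude: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra, MJ m^-2 d^-1 (FAO-56 geometry)."""
    return _solar_geometry(latitude, doy)[0]


def daylength(latitude: float, doy: int) -> float:
    """Maximum possible sunshine duration N, hours."""
    return 24.0 / math.pi * _solar_geometry(latitude, doy)[1]


def angstrom_radiation(sunshine_hours: float, latitude: float, doy: int,
                       a: float = 0.25, b: float = 0.50) -> float:
    """Angstrom conversion of sunshine duration to solar radiation.

    Rs = (a + b n/N) Ra, with Ra and N from standard solar geometry.
    """
    if sunshine_hours < 0:
        raise ValueError("sunshine hours must be non-negative")
    ra = extraterrestrial_radiation(latitude, doy)
    n_max = daylength(latitude, doy)
    if sunshine_hours > n_max + 1e-9:
        raise ValueError(
            f"sunshine {sunshine_hours:.2f} h exceeds daylength {n_max:.2f} h")
    frac = sunshine_hours / n_max if n_max > 0 else 0.0
    return (a + b * frac) * ra


# ---------------------------------------------------------------------------
# weather generator


def generate_weather(spec: ClimateSpec, start: dt.date, n_days: int,
                     seed) -> list[WeatherDay]:
    """Seeded daily weather series of length ``n_days`` from ``start``."""
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = np.random.default_rng(seed)
    irrigation = {d: mm for d, mm in spec.irrigation_events}
    out: list[WeatherDay] = []
    wet_prev = False
    for i in range(n_days):
        date = start + dt.timedelta(days=i)
        doy = date.timetuple().tm_yday
        month = date.month - 1
        p = spec.wet_prob_by_month[month]
        if p <= 0:
            wet = False
        else:
            p11 = min(0.9, p + spec.wet_persistence_boost)
            p01 = p * (1 - p11) / (1 - p) if p < 1 else 1.0
            p01 = min(1.0, p01)
            wet = rng.random() < (p11 if wet_prev else p01)
        rain = float(rng.exponential(spec.wet_depth_by_month[month])) if wet else 0.0
        wet_prev = wet

        tmean = (spec.t_mean - spec.t_amplitude
                 * math.cos(2.0 * math.pi * (doy - spec.t_phase_doy) / 365.0)
                 + rng.normal(0.0, spec.t_noise_sd))
        half = 0.5 * spec.diurnal_range
        a, b = (spec.sunshine_beta_wet if wet else spec.sunshine_beta_dry)
        frac = float(rng.beta(a, b))
        n_max = daylength(spec.latitude, doy)
        rad = angstrom_radiation(frac * n_max, spec.latitude, doy,
                                 spec.angstrom_a, spec.angstrom_b)
        out.append(WeatherDay(date=date, tmin=tmean - half, tmax=tmean + half,
                              rain=rain, irrigation=irrigation.get(date, 0.0),
                              radiation=rad))
    return out


# ---------------------------------------------------------------------------
# twin experiments


# sd of a standard normal clipped to [-2, 2]; dividing by it restores a
# unit sample sd after truncation
_TRUNC_SD = 0.95920


def _relative_noise(rng: np.random.Generator, rel_error: float) -> float:
    """Bounded multiplicative error draw with sd exactly ``rel_error``.

    The standard-normal draw is truncated at +/-2 and rescaled, bounding
    the relative error at ~2.1 sd. Retrieval products are quality-screened
    and never report values near zero; an unbounded Gaussian at 35%
    relative error would occasionally produce nonphysical (zero or
    negative) moisture retrievals.
    """
    z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
    return rel_error * z / _TRUNC_SD


def sample_observations(truth_lai: Mapping[dt.date, float],
                        truth_sm: Mapping[dt.date, float],
                        plan: ObservationPlan,
                        seed) -> list[ObservationRecord]:
    """Multiplicative-noise observations of a known truth.

    obs = truth * (1 + eps) with eps a truncated Gaussian relative error
    (sd = rel_error, bounded; see _relative_noise), clamped at zero; the
    optional additive SM bias emulates the surface-probe vs root-zone
    mismatch. Draws are independent across dates and variables.
    """
    rng = np.random.default_rng(seed)
    records: list[ObservationRecord] = []
    e_lai = plan.rel_errors.get("LAI", 0.0)
    for date in plan.lai_dates:
        v = truth_lai[date] * (1.0 + _relative_noise(rng, e_lai))
        records.append(ObservationRecord(date, "LAI", max(0.0, v), e_lai))
    e_sm = plan.rel_errors.get("SM", 0.0)
    for date in plan.sm_dates:
        v = truth_sm[date] * (1.0 + _relative_noise(rng, e_sm)) + plan.sm_bias
        v = min(max(0.0, v), 0.999)
        records.append(ObservationRecord(date, "SM", v, e_sm))
    records.sort(key=lambda r: (r.date, r.variable))
    return records


def generate_twin(crop: CropParams, soil: SoilParams,
                  weather: Sequence[WeatherDay], plan: ObservationPlan,
                  seed) -> tuple[SeasonResult, list[ObservationRecord]]:
    """Truth trajectory plus noisy observations on the plan's calendar."""
    truth = run_season(crop, soil, weather)
    traj = truth.trajectory
    dates = list(traj["date"])
    lai = dict(zip(dates, traj["lai"]))
    sm = dict(zip(dates, traj["sm"]))
    for d in (*plan.lai_dates, *plan.sm_dates):
        if d not in lai:
            raise ValueError(f"observation date {d} outside the weather window")
    obs = sample_observations(lai, sm, plan, seed)
    return truth, obs


# ---------------------------------------------------------------------------
# regional grid


def generate_region(spec: RegionalGridSpec, base_crop: CropParams,
                    base_soil: SoilParams, weather: Sequence[WeatherDay],
                    plan: ObservationPlan, seed) -> list[RegionalCell]:
    """Grid of cells with wheat fractions, jittered truths and observations.

    Wheat fractions are drawn uniformly on ``wheat_fraction_range``. Each
    cell's truth parameters jitter the six assimilation targets by
    ``param_jitter_sd`` (relative, Gaussian); the cell's observations are
    sampled from that truth on the shared plan. Weather is shared by all
    cells. With zero jitter all cells carry identical truths.
    """
    from .assimilation import DEFAULT_PERTURBATIONS, perturb_parameters

    ss = np.random.SeedSequence(_as_entropy(seed))
    frac_rng = np.random.default_rng(ss.spawn(1)[0])
    cells: list[RegionalCell] = []
    lo, hi = spec.wheat_fraction_range
    jitter = [p.__class__(p.target, spec.param_jitter_sd, p.distribution)
              for p in DEFAULT_PERTURBATIONS]
    truth_cache: tuple[SeasonResult, dict, dict] | None = None
    for row in range(spec.n_rows):
        for col in range(spec.n_cols):
            cell_ss = np.random.SeedSequence(
                entropy=_as_entropy(seed), spawn_key=(1, row, col))
            prng, orng = (np.random.default_rng(s) for s in cell_ss.spawn(2))
            frac = float(frac_rng.uniform(lo, hi))
            if spec.param_jitter_sd > 0:
                crop, soil_p = perturb_parameters(base_crop, base_soil,
                                                  jitter, prng)
                truth = run_season(crop, soil_p, weather)
                traj = truth.trajectory
                lai = dict(zip(traj["date"], traj["lai"]))
                sm = dict(zip(traj["date"], traj["sm"]))
            else:
                crop, soil_p = base_crop, base_soil
                if truth_cache is None:
                    truth = run_season(crop, soil_p, weather)
                    traj = truth.trajectory
                    truth_cache = (truth,
                                   dict(zip(traj["date"], traj["lai"])),
                                   dict(zip(traj["date"], traj["sm"])))
                truth, lai, sm = truth_cache
            obs = tuple(sample_observations(lai, sm, plan, orng))
            cells.append(RegionalCell(row=row, col=col, wheat_fraction=frac,
                                      truth_crop=crop, truth_soil=soil_p,
                                      truth_yield=truth.yield_kg_ha,
                                      observations=obs))
    return cells


def _as_entropy(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1, np.uint64)[0])
    return int(seed)


# ---------------------------------------------------------------------------
# defaults mirroring the study conditions


def default_climate(season_end_year: int = 2017) -> ClimateSpec:
    """Semi-humid climate with a dry winter and flood-irrigated wheat.

    The irrigation schedule follows regional winter wheat practice —
    roughly 60-75 mm per application at pre-winter, green-up, jointing,
    heading and milk filling — each refilling the root zone to around
    field capacity.
    """
    y = season_end_year
    return ClimateSpec(irrigation_events=(
        (dt.date(y - 1, 11, 25), 75.0),
        (dt.date(y, 3, 5), 75.0),
        (dt.date(y, 4, 5), 75.0),
        (dt.date(y, 5, 1), 75.0),
        (dt.date(y, 5, 20), 60.0),
    ))


def default_observation_plan(season_end_year: int = 2017) -> ObservationPlan:
    """Sentinel-cadence default: 7 LAI dates and 8 SM dates, late Feb-late May."""
    y = season_end_year
    lai = (dt.date(y, 2, 27), dt.date(y, 3, 9), dt.date(y, 3, 29),
           dt.date(y, 4, 18), dt.date(y, 4, 28), dt.date(y, 5, 18),
           dt.date(y, 5, 28))
    sm = (dt.date(y, 2, 25), dt.date(y, 3, 9), dt.date(y, 3, 21),
          dt.date(y, 4, 2), dt.date(y, 4, 14), dt.date(y, 4, 26),
          dt.date(y, 5, 8), dt.date(y, 5, 20))
    return ObservationPlan(lai_dates=lai, sm_dates=sm)
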
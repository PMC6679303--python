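"""Water-limited winter wheat growth simulator.

A reduced WOFOST-style model advanced on a daily time step. It keeps the
full mechanistic skeleton that state assimilation of leaf area index (LAI)
and root-zone soil moisture (SM) touches:

* thermal-time phenology (DVS: 0 emergence, 1 anthesis, 2 maturity),
* leaf-cohort LAI dynamics with SPAN/TBASE physiological ageing and an
  RGRLAI-capped juvenile exponential phase,
* Beer-law light interception with light-use-efficiency assimilation and
  Q10 maintenance respiration,
* DVS-indexed partitioning to roots, leaves, stems and storage organs,
* a one-layer free-draining soil-water bucket with transpiration- and
  evaporation-reduction factors between wilting point and field capacity.

Potential evapotranspiration uses a Hargreaves-type temperature-radiation
formula so that wind and humidity inputs remain optional. The model is a
pure function of its inputs: two identical calls give bitwise-identical
states, which the ensemble filter relies on.

Units: dry weights kg ha^-1, LAI dimensionless (specific leaf area in
ha kg^-1), soil moisture cm^3 cm^-3, water depths in cm inside the bucket
(weather rain/irrigation are mm d^-1), radiation MJ m^-2 d^-1,
temperatures deg C.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeatherDay",
    "PiecewiseTable",
    "CropParams",
    "SoilParams",
    "LeafCohort",
    "CropState",
    "WaterFluxes",
    "SeasonResult",
    "update_phenology",
    "update_leaves",
    "update_soil_water",
    "daily_growth",
    "advance_day",
    "run_season",
    "initial_state",
    "potential_evapotranspiration",
    "default_crop_params",
    "default_soil_params",
]

# Leaves at 35 degC age by exactly one physiological day per calendar day,
# so a leaf born at constant 35 degC lives exactly SPAN days.
_AGEING_REFERENCE_TEMP = 35.0


class PiecewiseTable:
    """Piecewise-linear lookup table over DVS, given as [[dvs, value], ...].

    Values are held constant outside the knot range (np.interp semantics).
    """

    __slots__ = ("x", "y")

    def __init__(self, knots: Sequence[Sequence[float]] | "PiecewiseTable"):
        if isinstance(knots, PiecewiseTable):
            self.x, self.y = knots.x, knots.y
            return
        arr = np.asarray(knots, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError("table needs at least two [x, y] knots")
        if np.any(np.diff(arr[:, 0]) < 0):
            raise ValueError("table knots must be sorted by x")
        self.x = arr[:, 0].copy()
        self.y = arr[:, 1].copy()

    def __call__(self, x: float) -> float:
        return float(np.interp(x, self.x, self.y))

    def to_knots(self) -> list[list[float]]:
        return [[float(a), float(b)] for a, b in zip(self.x, self.y)]

    def __eq__(self, other):
        return (
            isinstance(other, PiecewiseTable)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
        )

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"PiecewiseTable({self.to_knots()})"


@dataclass(frozen=True, slots=True)
class WeatherDay:
    """One day of forcing. rain and irrigation are mm d^-1 water depth."""

    date: dt.date
    tmin: float
    tmax: float
    rain: float
    irrigation: float = 0.0
    radiation: float = 0.0  # MJ m^-2 d^-1 total shortwave
    wind: float | None = None  # m s^-1, unused by the Hargreaves-type ET

    def __post_init__(self):
        if self.tmax < self.tmin:
            raise ValueError(f"{self.date}: tmax {self.tmax} < tmin {self.tmin}")
        if self.rain < 0 or self.irrigation < 0 or self.radiation < 0:
            raise ValueError(f"{self.date}: negative rain/irrigation/radiation")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmin + self.tmax)


def _as_table(v):
    return v if isinstance(v, PiecewiseTable) else PiecewiseTable(v)


@dataclass(frozen=True)
class CropParams:
    """Crop parameter set (WOFOST naming).

    TDWI    initial total crop dry weight, kg ha^-1
    RGRLAI  maximum relative LAI growth rate, (degC d)^-1, juvenile cap
    SPAN    maximum leaf age at 35 degC, d
    TBASE   lower threshold temperature for leaf ageing, degC
    SLATB   specific leaf area vs DVS, ha kg^-1
    TSUM1/TSUM2/TBASEM  thermal-time phenology, degC d / degC
    FLTB/FSTB/FOTB      shoot partitioning fractions vs DVS (sum to 1)
    FRTB    root fraction of total growth vs DVS
    k_ext   canopy light extinction coefficient
    LUE     light-use efficiency, g dry matter per MJ intercepted PAR
    """

    TDWI: float = 210.0
    RGRLAI: float = 0.00817
    SPAN: float = 31.3
    TBASE: float = 0.0
    SLATB: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable([[0.0, 0.00212], [2.0, 0.00212]])
    )
    TSUM1: float = 1000.0
    TSUM2: float = 900.0
    TBASEM: float = 0.0
    FLTB: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(
            [[0.0, 0.65], [0.25, 0.70], [0.50, 0.50], [0.65, 0.30],
             [0.70, 0.25], [0.95, 0.00], [1.05, 0.00], [2.0, 0.00]]
        )
    )
    FSTB: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(
            [[0.0, 0.35], [0.25, 0.30], [0.50, 0.50], [0.65, 0.70],
             [0.70, 0.75], [0.95, 0.20], [1.05, 0.00], [2.0, 0.00]]
        )
    )
    FOTB: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(
            [[0.0, 0.00], [0.25, 0.00], [0.50, 0.00], [0.65, 0.00],
             [0.70, 0.00], [0.95, 0.80], [1.05, 1.00], [2.0, 1.00]]
        )
    )
    FRTB: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(
            [[0.0, 0.50], [0.25, 0.35], [0.50, 0.20], [0.70, 0.10],
             [1.0, 0.00], [2.0, 0.00]]
        )
    )
    k_ext: float = 0.60
    LUE: float = 3.0
    # temperature reduction of gross assimilation vs daily mean temperature
    TMPFTB: PiecewiseTable = field(
        default_factory=lambda: PiecewiseTable(
            [[0.0, 0.00], [10.0, 0.60], [15.0, 1.00], [25.0, 1.00],
             [35.0, 0.60]]
        )
    )
    # maximum relative death rate of leaves due to water stress, d^-1
    # (full rate at complete stomatal closure, zero when unstressed)
    PERDL: float = 0.030
    # maintenance respiration coefficients at 25 degC, kg kg^-1 d^-1
    RML: float = 0.030
    RMS: float = 0.015
    RMO: float = 0.010
    RMR: float = 0.015
    Q10: float = 2.0
    # juvenile (sink-limited, exponential) phase ends at the first of these
    JUV_DVS: float = 0.3
    JUV_LAI: float = 0.75
    # initial partition of TDWI over roots / leaves / stems
    FR_INIT: float = 0.50
    FL_INIT: float = 0.30
    FS_INIT: float = 0.20

    def __post_init__(self):
        for name in ("SLATB", "FLTB", "FSTB", "FOTB", "FRTB", "TMPFTB"):
            object.__setattr__(self, name, _as_table(getattr(self, name)))
        for name in ("TDWI", "RGRLAI", "SPAN", "TSUM1", "TSUM2", "k_ext", "LUE"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.TBASE >= _AGEING_REFERENCE_TEMP:
            raise ValueError("TBASE must lie below the 35 degC ageing reference")
        if not math.isclose(self.FR_INIT + self.FL_INIT + self.FS_INIT, 1.0,
                            abs_tol=1e-9):
            raise ValueError("initial TDWI partition must sum to 1")
        # shoot fractions must sum to 1 at every knot of the union grid
        grid = np.union1d(np.union1d(self.FLTB.x, self.FSTB.x), self.FOTB.x)
        for d in grid:
            fl, fs, fo = self.FLTB(d), self.FSTB(d), self.FOTB(d)
            for f in (fl, fs, fo):
                if f < -1e-9 or f > 1 + 1e-9:
                    raise ValueError("partition fractions must lie in [0, 1]")
            if abs(fl + fs + fo - 1.0) > 1e-6:
                raise ValueError(
                    f"shoot partition fractions do not sum to 1 at DVS={d:g}"
                )
            if not 0.0 - 1e-9 <= self.FRTB(d) <= 1.0 + 1e-9:
                raise ValueError("root fraction must lie in [0, 1]")


@dataclass(frozen=True, slots=True)
class SoilParams:
    """One-layer bucket soil.

    SM0/SMFCF/SMW  saturation / field capacity / wilting point, cm^3 cm^-3
    RD    rooting (bucket) depth, cm
    WAV   initial plant-available water, cm
    KSUB  maximum percolation rate below field capacity excess, cm d^-1
    """

    SM0: float = 0.46
    SMFCF: float = 0.32
    SMW: float = 0.12
    RD: float = 50.0
    WAV: float = 10.0
    KSUB: float = 3.0

    def __post_init__(self):
        if not (0.0 < self.SMW < self.SMFCF < self.SM0 < 1.0):
            raise ValueError("need 0 < SMW < SMFCF < SM0 < 1")
        if self.RD <= 0 or self.KSUB < 0:
            raise ValueError("RD must be positive and KSUB non-negative")
        if not (0.0 <= self.WAV <= (self.SM0 - self.SMW) * self.RD):
            raise ValueError("WAV outside [0, (SM0 - SMW) * RD]")

    @property
    def sm_crit(self) -> float:
        """Critical moisture below which transpiration is reduced."""
        return self.SMW + 0.5 * (self.SMFCF - self.SMW)


@dataclass(frozen=True, slots=True)
class LeafCohort:
    weight: float  # kg ha^-1
    age: float  # physiological days
    sla: float  # ha kg^-1 at birth


_EMPTY = np.empty(0)


@dataclass(slots=True)
class CropState:
    """Full daily model state.

    Leaf cohorts are stored oldest-first in parallel arrays; because every
    living cohort ages by the same increment each day, ages stay sorted
    descending and senescence removes a prefix.

    ``lai`` is stored explicitly (not recomputed on access) so that the
    filter can overwrite it; ``reconcile`` keeps lai == sum(w_i * sla_i).
    """

    dvs: float = 0.0
    tsum: float = 0.0
    leaf_w: np.ndarray = field(default_factory=lambda: _EMPTY.copy())
    leaf_age: np.ndarray = field(default_factory=lambda: _EMPTY.copy())
    leaf_sla: np.ndarray = field(default_factory=lambda: _EMPTY.copy())
    lai: float = 0.0
    wlv: float = 0.0
    wst: float = 0.0
    wso: float = 0.0
    wrt: float = 0.0
    tagp: float = 0.0
    sm: float = 0.25
    day_index: int = 0

    def copy(self) -> "CropState":
        # shallow array copy is safe: operations replace arrays, never
        # mutate them in place
        return CropState(self.dvs, self.tsum, self.leaf_w, self.leaf_age,
                         self.leaf_sla, self.lai, self.wlv, self.wst,
                         self.wso, self.wrt, self.tagp, self.sm,
                         self.day_index)

    @property
    def cohorts(self) -> list[LeafCohort]:
        return [LeafCohort(float(w), float(a), float(s))
                for w, a, s in zip(self.leaf_w, self.leaf_age, self.leaf_sla)]


@dataclass(frozen=True, slots=True)
class WaterFluxes:
    """End-of-day water-balance terms, all cm d^-1."""

    rain: float
    irrigation: float
    evaporation: float
    transpiration: float
    percolation: float
    runoff: float
    delta_w: float

    @property
    def residual(self) -> float:
        return (self.rain + self.irrigation - self.evaporation
                - self.transpiration - self.percolation - self.runoff
                - self.delta_w)


@dataclass(slots=True)
class SeasonResult:
    trajectory: pd.DataFrame  # columns day,date,dvs,lai,sm,tagp,wso
    yield_kg_ha: float
    maturity_day: int | None
    final_state: CropState
    fluxes: list[WaterFluxes] | None = None

    def value_at(self, date: dt.date, column: str) -> float:
        row = self.trajectory.loc[self.trajectory["date"] == date, column]
        if row.empty:
            raise KeyError(f"no trajectory row for {date}")
        return float(row.iloc[0])

    def to_csv(self, path) -> None:
        self.trajectory.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# process operations


def update_phenology(state: CropState, params: CropParams,
                     wd: WeatherDay) -> CropState:
    """Advance thermal time and development stage.

    DVS increases linearly with effective temperature, reaching 1 at TSUM1
    (anthesis) and 2 at TSUM1 + TSUM2 (maturity); it never decreases and is
    capped at 2.
    """
    teff = wd.tmean - params.TBASEM
    if teff < 0.0:
        teff = 0.0
    tsum = state.tsum + teff
    if tsum <= params.TSUM1:
        dvs = tsum / params.TSUM1
    else:
        dvs = 1.0 + (tsum - params.TSUM1) / params.TSUM2
    if dvs > 2.0:
        dvs = 2.0
    if dvs < state.dvs:
        dvs = state.dvs
    new = state.copy()
    new.tsum = tsum
    new.dvs = dvs
    return new


def update_leaves(state: CropState, params: CropParams, wd: WeatherDay,
                  new_leaf_dw: float, water_stress: float = 1.0) -> CropState:
    """Age cohorts, drop those beyond SPAN, append the day's new cohort.

    Cohorts age by (Tmean - TBASE)/(35 - TBASE) physiological days per
    calendar day (no ageing at or below TBASE). Water stress additionally
    kills a fraction PERDL * (1 - water_stress) of every living cohort per
    day (drought-induced senescence). During the juvenile phase
    (dvs < JUV_DVS and lai < JUV_LAI) leaf-area growth is additionally
    sink-limited to lai * (exp(RGRLAI * dTeff) - 1); assimilate beyond the
    cap is discarded (the exponential phase is short and the excess small).
    """
    if new_leaf_dw < 0:
        raise ValueError("negative leaf growth: partitioning bug upstream")
    tmean = wd.tmean
    ageing = tmean - params.TBASE
    ageing = ageing / (_AGEING_REFERENCE_TEMP - params.TBASE) if ageing > 0 else 0.0
    age = state.leaf_age + ageing if ageing else state.leaf_age
    w, sla = state.leaf_w, state.leaf_sla

    dead_w = 0.0
    if age.size and age[0] > params.SPAN:
        alive = age <= params.SPAN
        k = int(np.argmax(alive)) if alive.any() else age.size
        dead_w = float(w[:k].sum())
        w, age, sla = w[k:], age[k:], sla[k:]

    death = params.PERDL * (1.0 - water_stress)
    if death > 0.0 and w.size:
        dead_w += float(w.sum()) * death
        w = w * (1.0 - death)

    grow = new_leaf_dw
    if state.dvs < params.JUV_DVS and state.lai < params.JUV_LAI:
        dteff = max(0.0, tmean - params.TBASE)
        cap = state.lai * (math.exp(params.RGRLAI * dteff) - 1.0)
        sla_new = params.SLATB(state.dvs)
        grow = min(grow, cap / sla_new) if sla_new > 0 else 0.0

    if grow > 0.0:
        w = np.append(w, grow)
        age = np.append(age, 0.0)
        sla = np.append(sla, params.SLATB(state.dvs))

    new = state.copy()
    new.leaf_w, new.leaf_age, new.leaf_sla = w, age, sla
    new.lai = float(w @ sla) if w.size else 0.0
    new.wlv = max(0.0, state.wlv - dead_w + grow)
    return new


def update_soil_water(state: CropState, soil: SoilParams, wd: WeatherDay,
                      evap_demand: float, transp_demand: float
                      ) -> tuple[CropState, WaterFluxes]:
    """One day of the free-draining bucket. Demands are potential E and T, cm.

    Order of terms: infiltration of rain + irrigation, then actual E and T
    (demand times a linear soil-moisture reduction factor, jointly capped so
    the bucket cannot fall below wilting point), then percolation of the
    excess above field capacity (rate-limited by KSUB), then surface runoff
    of anything above saturation. Reduction factors are evaluated at the
    start-of-day moisture.
    """
    if evap_demand < 0 or transp_demand < 0:
        raise ValueError("ET demands must be non-negative")
    rd = soil.RD
    w0 = state.sm * rd
    rain_cm = wd.rain * 0.1
    irr_cm = wd.irrigation * 0.1
    w = w0 + rain_cm + irr_cm

    span_t = soil.sm_crit - soil.SMW
    span_e = soil.SMFCF - soil.SMW
    f_t = min(1.0, max(0.0, (state.sm - soil.SMW) / span_t))
    f_e = min(1.0, max(0.0, (state.sm - soil.SMW) / span_e))
    e_act = evap_demand * f_e
    t_act = transp_demand * f_t
    avail = w - soil.SMW * rd
    if avail < 0.0:
        avail = 0.0
    total = e_act + t_act
    if total > avail and total > 0.0:
        scale = avail / total
        e_act *= scale
        t_act *= scale
    w -= e_act + t_act

    perc = w - soil.SMFCF * rd
    perc = min(soil.KSUB, perc) if perc > 0.0 else 0.0
    w -= perc
    runoff = w - soil.SM0 * rd
    runoff = runoff if runoff > 0.0 else 0.0
    w -= runoff

    new = state.copy()
    new.sm = min(max(w / rd, soil.SMW), soil.SM0)
    fluxes = WaterFluxes(rain_cm, irr_cm, e_act, t_act, perc, runoff,
                         new.sm * rd - w0)
    return new, fluxes


def daily_growth(state: CropState, params: CropParams, wd: WeatherDay,
                 water_stress: float) -> tuple[CropState, float]:
    """Assimilate, respire and partition one day's growth.

    Gross growth = LUE * intercepted PAR * water_stress (PAR taken as half
    the shortwave total); Q10 maintenance respiration is subtracted and net
    growth floored at zero. Roots take FRTB(dvs) of the net; the shoot rest
    is split by FLTB/FSTB/FOTB. Growth stops at maturity (dvs >= 2).

    Returns the updated state and the leaf dry-matter increment, which
    update_leaves turns into a new cohort.
    """
    if not 0.0 <= water_stress <= 1.0:
        raise ValueError("water_stress must lie in [0, 1]")
    if state.dvs >= 2.0:
        net = 0.0
    else:
        par = 0.5 * wd.radiation
        intercepted = 1.0 - math.exp(-params.k_ext * state.lai)
        # daytime temperature (mean of tmax and tmean) drives assimilation
        tfac = params.TMPFTB(0.5 * (wd.tmax + wd.tmean))
        gross = 10.0 * params.LUE * par * intercepted * tfac * water_stress  # kg/ha
        maint = (params.Q10 ** ((wd.tmean - 25.0) * 0.1)) * (
            params.RML * state.wlv + params.RMS * state.wst
            + params.RMO * state.wso + params.RMR * state.wrt)
        net = gross - maint
        if net < 0.0:
            net = 0.0
    fr = params.FRTB(state.dvs)
    shoot = net * (1.0 - fr)
    new = state.copy()
    new.wrt = state.wrt + net * fr
    new.wst = state.wst + shoot * params.FSTB(state.dvs)
    new.wso = state.wso + shoot * params.FOTB(state.dvs)
    new.tagp = new.wlv + new.wst + new.wso
    return new, shoot * params.FLTB(state.dvs)


def potential_evapotranspiration(wd: WeatherDay) -> float:
    """Hargreaves-type reference ET (mm d^-1) from temperature and radiation.

    ET0 = 0.0135 (Tmean + 17.78) * Rs, with Rs converted to mm d^-1
    evaporation equivalent (1 MJ m^-2 = 0.408 mm). A swap-in point for
    Penman-Monteith when wind and humidity data are available.
    """
    et0 = 0.0135 * (wd.tmean + 17.78) * 0.408 * wd.radiation
    return et0 if et0 > 0.0 else 0.0


def advance_day(state: CropState, params: CropParams, soil: SoilParams,
                wd: WeatherDay) -> CropState:
    """One application of the model operator M: full daily update.

    Composes potential-ET partitioning by canopy cover, the soil-water
    bucket, the transpiration-deficit stress factor, assimilation and
    partitioning, leaf-cohort dynamics, and phenology — in that order.
    """
    et0_cm = potential_evapotranspiration(wd) * 0.1
    cover = 1.0 - math.exp(-params.k_ext * state.lai)
    e_pot = et0_cm * (1.0 - cover)
    t_pot = et0_cm * cover
    s, fluxes = update_soil_water(state, soil, wd, e_pot, t_pot)
    if t_pot > 1e-12:
        stress = fluxes.transpiration / t_pot
        stress = min(1.0, max(0.0, stress))
    else:
        stress = 1.0
    s, leaf_dw = daily_growth(s, params, wd, stress)
    s = update_leaves(s, params, wd, leaf_dw, water_stress=stress)
    s = update_phenology(s, params, wd)
    s.tagp = s.wlv + s.wst + s.wso
    s.day_index = state.day_index + 1
    return s


def _advance_day_with_fluxes(state, params, soil, wd):
    et0_cm = potential_evapotranspiration(wd) * 0.1
    cover = 1.0 - math.exp(-params.k_ext * state.lai)
    s, fluxes = update_soil_water(state, soil, wd, et0_cm * (1.0 - cover),
                                  et0_cm * cover)
    t_pot = et0_cm * cover
    if t_pot > 1e-12:
        stress = min(1.0, max(0.0, fluxes.transpiration / t_pot))
    else:
        stress = 1.0
    s, leaf_dw = daily_growth(s, params, wd, stress)
    s = update_leaves(s, params, wd, leaf_dw, water_stress=stress)
    s = update_phenology(s, params, wd)
    s.tagp = s.wlv + s.wst + s.wso
    s.day_index = state.day_index + 1
    return s, fluxes


def initial_state(params: CropParams, soil: SoilParams) -> CropState:
    """State at emergence: TDWI split over organs, WAV filling the bucket."""
    wrt = params.FR_INIT * params.TDWI
    wlv = params.FL_INIT * params.TDWI
    wst = params.FS_INIT * params.TDWI
    sla0 = params.SLATB(0.0)
    if wlv > 0.0:
        leaf_w = np.array([wlv])
        leaf_age = np.array([0.0])
        leaf_sla = np.array([sla0])
        lai = wlv * sla0
    else:
        leaf_w = leaf_age = leaf_sla = _EMPTY.copy()
        lai = 0.0
    sm = min(soil.SMW + soil.WAV / soil.RD, soil.SM0)
    return CropState(dvs=0.0, tsum=0.0, leaf_w=leaf_w, leaf_age=leaf_age,
                     leaf_sla=leaf_sla, lai=lai, wlv=wlv, wst=wst, wso=0.0,
                     wrt=wrt, tagp=wlv + wst, sm=sm, day_index=0)


def run_season(params: CropParams, soil: SoilParams,
               weather: Sequence[WeatherDay],
               sowing_day: dt.date | None = None,
               collect_fluxes: bool = False) -> SeasonResult:
    """Simulate one season and return the daily trajectory and yield.

    ``sowing_day`` selects the first simulated day within ``weather``
    (default: the first weather day). Day 0 is emergence. Yield is the
    storage-organ weight at maturity, or at the last weather day if
    maturity (DVS = 2) is not reached.
    """
    weather = list(weather)
    if sowing_day is not None:
        start = next((i for i, wd in enumerate(weather)
                      if wd.date >= sowing_day), None)
        if start is None:
            raise ValueError("weather series does not cover the sowing day")
        weather = weather[start:]
    if not weather:
        raise ValueError("empty weather series")

    state = initial_state(params, soil)
    n = len(weather)
    days = np.empty(n, dtype=int)
    dvs = np.empty(n)
    lai = np.empty(n)
    sm = np.empty(n)
    tagp = np.empty(n)
    wso = np.empty(n)
    dates: list[dt.date] = []
    fluxes: list[WaterFluxes] | None = [] if collect_fluxes else None
    maturity_day: int | None = None

    for i, wd in enumerate(weather):
        if collect_fluxes:
            state, fx = _advance_day_with_fluxes(state, params, soil, wd)
            fluxes.append(fx)
        else:
            state = advance_day(state, params, soil, wd)
        days[i] = state.day_index
        dates.append(wd.date)
        dvs[i] = state.dvs
        lai[i] = state.lai
        sm[i] = state.sm
        tagp[i] = state.tagp
        wso[i] = state.wso
        if maturity_day is None and state.dvs >= 2.0:
            maturity_day = state.day_index

    traj = pd.DataFrame({"day": days, "date": dates, "dvs": dvs, "lai": lai,
                         "sm": sm, "tagp": tagp, "wso": wso})
    return SeasonResult(trajectory=traj, yield_kg_ha=float(state.wso),
                        maturity_day=maturity_day, final_state=state,
                        fluxes=fluxes)


def default_crop_params(**overrides) -> CropParams:
    """Winter wheat defaults in the style of the standard WOFOST set."""
    return dataclasses.replace(CropParams(), **overrides) if overrides else CropParams()


def default_soil_params(**overrides) -> SoilParams:
    """Fluvo-aquic loam defaults for a North China Plain root zone."""
    return dataclasses.replace(SoilParams(), **overrides) if overrides else SoilParams()
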
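"""Twin-experiment study drivers shared by the analysis scripts and tests.

A twin experiment replaces the field campaign: a truth run of the crop
model (with parameters drawn from the same 10% Gaussian prior the ensemble
uses) generates Sentinel-cadence noisy pseudo-observations, the four
schemes are run against them under identical conditions, and skill is
measured against the known truth.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assimilation import (DEFAULT_PERTURBATIONS, Scheme, SchemeConfig,
                           AssimilationResult, perturb_parameters,
                           run_all_schemes)
from .crop_model import (CropParams, SeasonResult, SoilParams,
                         default_crop_params, default_soil_params, run_season)
from .synthetic_data import (ClimateSpec, ObservationPlan, ObservationRecord,
                             default_climate, default_observation_plan,
                             generate_twin, generate_weather)

__all__ = [
    "TwinResult",
    "default_season",
    "run_twin",
    "scheme_error_study",
    "study_summary",
]

#: sowing (emergence) date and season length of the default study season:
#: early-October sowing through mid-June harvest.
DEFAULT_SOWING = dt.date(2016, 10, 10)
DEFAULT_SEASON_DAYS = 249  # through 2017-06-15

ALL_SCHEMES = (Scheme.OPEN_LOOP, Scheme.DA_LAI, Scheme.DA_SM, Scheme.DA_JOINT)


@dataclass
class TwinResult:
    seed: int
    truth: SeasonResult
    truth_crop: CropParams
    truth_soil: SoilParams
    observations: list[ObservationRecord]
    results: dict[Scheme, AssimilationResult]

    def trajectory_rmse(self, scheme: Scheme, column: str) -> float:
        """Daily RMSE of the ensemble-mean trajectory against truth."""
        mean = self.results[scheme].daily[f"{column}_mean"].to_numpy()
        truth = self.truth.trajectory[column].to_numpy()
        return float(np.sqrt(np.mean((mean - truth) ** 2)))

    def yield_error(self, scheme: Scheme) -> float:
        """Ensemble-median yield minus truth yield.

        The ensemble median is the point estimate matched to the absolute
        -error loss used throughout the study; the ensemble mean is biased
        low by the concavity of yield in the water-related parameters.
        """
        return float(self.results[scheme].yield_median
                     - self.truth.yield_kg_ha)


def default_season(seed, climate: ClimateSpec | None = None,
                   sowing: dt.date = DEFAULT_SOWING,
                   n_days: int = DEFAULT_SEASON_DAYS):
    """Weather for the default study window (sowing to mid-June)."""
    climate = climate or default_climate(sowing.year + 1)
    return generate_weather(climate, sowing, n_days, seed)


def _child_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master) % (2 ** 31),
                                  spawn_key=tuple(key))


def perturb_forcing(weather, rng, irrigation_sd: float = 0.30,
                    rain_sd: float = 0.0,
                    irrigation_bounds: tuple[float, float] = (0.4, 1.6)):
    """Perturb the water inputs of a weather series.

    Emulates the unobserved field-scale water inputs: the model is driven
    by the nominal irrigation schedule and county-station rainfall, while
    the true crop received farmer-specific irrigation amounts (Gaussian
    factor N(1, irrigation_sd) clipped to ``irrigation_bounds``) and local
    rainfall (mean-one lognormal factor with logarithmic sd ``rain_sd``
    per wet day).
    """
    out = []
    for wd in weather:
        irr, rain = wd.irrigation, wd.rain
        changed = False
        if irrigation_sd > 0 and irr > 0:
            irr *= float(np.clip(1.0 + irrigation_sd * rng.standard_normal(),
                                 *irrigation_bounds))
            changed = True
        if rain_sd > 0 and rain > 0:
            rain *= float(np.exp(rain_sd * rng.standard_normal()
                                 - 0.5 * rain_sd ** 2))
            changed = True
        out.append(dataclasses.replace(wd, irrigation=irr, rain=rain)
                   if changed else wd)
    return out


def run_twin(seed: int,
             base_crop: CropParams | None = None,
             base_soil: SoilParams | None = None,
             climate: ClimateSpec | None = None,
             plan: ObservationPlan | None = None,
             ensemble_size: int = 50,
             schemes: Sequence[Scheme] = ALL_SCHEMES,
             perturbations=DEFAULT_PERTURBATIONS,
             truth_perturbations=None,
             irrigation_uncertainty_sd: float = 0.30,
             rain_uncertainty_sd: float = 0.0,
             perturbation_mode: str = "second_order",
             config_overrides: dict | None = None) -> TwinResult:
    """One complete twin experiment under the study's default conditions.

    The truth run differs from the assimilating model in two ways the
    filter knows nothing about beyond its parameter prior: its six
    perturbation targets are drawn from that 10% prior, and its irrigation
    depths deviate from the nominal schedule by ``irrigation_uncertainty_sd``
    (unobserved input uncertainty; the filter itself runs with Q = 0).

    The master seed is split into independent streams for weather
    generation, the truth parameter draw, observation noise and the
    filter's own randomness, so any piece can be reproduced in isolation.
    """
    base_crop = base_crop or default_crop_params()
    base_soil = base_soil or default_soil_params()
    plan = plan or default_observation_plan(DEFAULT_SOWING.year + 1)

    weather = default_season(_child_seed(seed, 0), climate)
    truth_rng = np.random.default_rng(_child_seed(seed, 1))
    truth_crop, truth_soil = perturb_parameters(
        base_crop, base_soil,
        perturbations if truth_perturbations is None else truth_perturbations,
        truth_rng)
    truth_weather = perturb_forcing(weather, truth_rng,
                                    irrigation_uncertainty_sd,
                                    rain_uncertainty_sd)
    truth, obs = generate_twin(truth_crop, truth_soil, truth_weather, plan,
                               _child_seed(seed, 2))
    cfg = SchemeConfig(ensemble_size=ensemble_size,
                       perturbations=tuple(perturbations),
                       seed=int(_child_seed(seed, 3).generate_state(1)[0]
                                % (2 ** 31)),
                       perturbation_mode=perturbation_mode,
                       **(config_overrides or {}))
    results = run_all_schemes(cfg, base_crop, base_soil, weather, obs,
                              schemes=schemes)
    return TwinResult(seed=seed, truth=truth, truth_crop=truth_crop,
                      truth_soil=truth_soil, observations=obs,
                      results=results)


def scheme_error_study(n_seeds: int = 30, master_seed: int = 0,
                       ensemble_size: int = 50,
                       schemes: Sequence[Scheme] = ALL_SCHEMES,
                       collect_events: bool = True,
                       **twin_kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate the twin experiment over ``n_seeds`` independent seasons.

    Returns (per-seed table, per-event audit). The per-seed table has one
    row per (seed, scheme) with the absolute and relative yield error and
    the LAI/SM trajectory RMSEs; the audit stacks every analysis event's
    prior/posterior variance for the contraction check.
    """
    rows = []
    audits = []
    base = np.random.SeedSequence(int(master_seed) % (2 ** 31))
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in base.spawn(n_seeds)]
    for seed in seeds:
        twin = run_twin(seed, ensemble_size=ensemble_size, schemes=schemes,
                        **twin_kwargs)
        ty = twin.truth.yield_kg_ha
        for scheme in schemes:
            res = twin.results[scheme]
            err = res.yield_median - ty
            rows.append({
                "seed": seed, "scheme": scheme.value,
                "truth_yield": ty, "yield_mean": res.yield_mean,
                "yield_median": res.yield_median,
                "yield_err": err, "abs_yield_err": abs(err),
                "rel_yield_err_pct": abs(err) / ty * 100.0 if ty else np.nan,
                "lai_rmse": twin.trajectory_rmse(scheme, "lai"),
                "sm_rmse": twin.trajectory_rmse(scheme, "sm"),
            })
            if collect_events and len(res.events):
                ev = res.events.copy()
                ev.insert(0, "scheme", scheme.value)
                ev.insert(0, "seed", seed)
                audits.append(ev)
    per_seed = pd.DataFrame(rows)
    audit = (pd.concat(audits, ignore_index=True) if audits
             else pd.DataFrame())
    return per_seed, audit


def study_summary(per_seed: pd.DataFrame) -> pd.DataFrame:
    """Median per-scheme skill over the replicate seasons."""
    g = per_seed.groupby("scheme")
    out = g.agg(median_abs_yield_err=("abs_yield_err", "median"),
                median_rel_yield_err_pct=("rel_yield_err_pct", "median"),
                median_lai_rmse=("lai_rmse", "median"),
                median_sm_rmse=("sm_rmse", "median"),
                n=("seed", "count")).reset_index()
    order = {s.value: i for i, s in enumerate(ALL_SCHEMES)}
    out["order"] = out["scheme"].map(order)
    return out.sort_values("order").drop(columns="order").reset_index(drop=True)
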
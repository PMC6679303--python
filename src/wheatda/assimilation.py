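"""Experiment orchestration: open-loop and the three assimilation schemes.

Runs an Ne-member ensemble of the crop model day by day and, at every
observation date matching the scheme, applies the EnKF analysis to the
(LAI, SM) state subvector of every member, then reconciles the full crop
state (cohort rescaling, moisture clamping) with the updated values.

Schemes: OPEN_LOOP (no analyses), DA_LAI (LAI records only), DA_SM (SM
records only), DA_JOINT (both; records sharing a date are stacked into one
two-variable observation). Ensemble members draw their six perturbation
targets (TDWI, WAV, RGRLAI, SPAN, SMFCF, SM0) from independent Gaussians
with 10% relative sd by default. One master seed is split into independent
streams for ensemble building and observation perturbation, so schemes
with the same seed share an identical initial ensemble.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import enkf
from .crop_model import (CropParams, CropState, SoilParams, WeatherDay,
                         advance_day, initial_state)
from .synthetic_data import ObservationRecord

__all__ = [
    "Scheme",
    "PerturbationSpec",
    "SchemeConfig",
    "AssimilationResult",
    "DEFAULT_PERTURBATIONS",
    "STATE_LABELS",
    "perturb_parameters",
    "build_ensemble",
    "observation_variance",
    "reconcile_state",
    "run_scheme",
    "run_all_schemes",
]

STATE_LABELS = ("LAI", "SM")

_CROP_TARGETS = ("TDWI", "RGRLAI", "SPAN")
_SOIL_TARGETS = ("WAV", "SMFCF", "SM0")


class Scheme(str, enum.Enum):
    OPEN_LOOP = "open_loop"
    DA_LAI = "lai"
    DA_SM = "sm"
    DA_JOINT = "joint"

    @property
    def observed_variables(self) -> tuple[str, ...]:
        return {"open_loop": (), "lai": ("LAI",), "sm": ("SM",),
                "joint": ("LAI", "SM")}[self.value]


@dataclass(frozen=True)
class PerturbationSpec:
    """Gaussian relative perturbation of one parameter or initial value."""

    target: str
    relative_sd: float = 0.10
    distribution: str = "gaussian"

    def __post_init__(self):
        if self.target not in _CROP_TARGETS + _SOIL_TARGETS:
            raise ValueError(f"unknown perturbation target {self.target!r}")
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be non-negative")
        if self.distribution != "gaussian":
            raise ValueError("only Gaussian perturbations are supported")


DEFAULT_PERTURBATIONS: tuple[PerturbationSpec, ...] = tuple(
    PerturbationSpec(t, 0.10) for t in _CROP_TARGETS + _SOIL_TARGETS)


@dataclass(frozen=True)
class SchemeConfig:
    """One experiment definition."""

    scheme: Scheme = Scheme.OPEN_LOOP
    ensemble_size: int = 50
    perturbations: tuple[PerturbationSpec, ...] = DEFAULT_PERTURBATIONS
    obs_rel_error: Mapping[str, float] = field(
        default_factory=lambda: {"LAI": 0.10, "SM": 0.35})
    seed: int = 0
    variance_floor: float = 1e-6  # keeps R invertible at near-zero values
    perturbation_mode: str = "second_order"
    # Reference value for the relative-error rule. "observed" applies it to
    # the observation itself; "max_forecast" (default) applies it to
    # max(observed, forecast mean), which guards against over-trusting an
    # observation whose own (multiplicative) error pushed it low — with
    # purely observed-value variances, low-noise draws get small R and
    # large gains, biasing the analysis downward.
    variance_reference: str = "max_forecast"
    # Background quality control: reject an observation whose innovation
    # exceeds this many sqrt(HPfH' + R); None disables the check. The
    # default (3) is the conventional gross-error gate; it protects the
    # filter from the occasional large multiplicative error draw whose own
    # low value would otherwise shrink its assigned variance.
    qc_innovation_sd: float | None = 3.0
    # Relative sds of the per-member water-input forcing perturbations (the
    # uncertain input alpha of the forecast model). Field-scale irrigation
    # amounts and field-scale rainfall are not known to the model (one
    # weather station per county); spreading the ensemble over them keeps
    # the forecast SM spread consistent with that input uncertainty.
    # Irrigation factors are Gaussian (clipped); rain factors are mean-one
    # lognormal per wet day. Zero disables either perturbation.
    irrigation_forcing_sd: float = 0.30
    irrigation_forcing_bounds: tuple[float, float] = (0.4, 1.6)
    rain_forcing_sd: float = 0.0
    # Variable localisation: zero the cross-variable gain entries so an SM
    # observation updates only SM (and vice versa). At Ne = 50 the sampled
    # instantaneous LAI-SM cross-covariance is dominated by noise — SM has
    # days of memory while LAI integrates stress over weeks — so the
    # cross-variable channel is left to the model dynamics.
    localize_cross_updates: bool = True
    # Adaptive spread calibration (Desroziers-style): a per-variable factor
    # lambda scaling the forecast variance used in the gain, updated after
    # every event from the innovation consistency ratio
    # lambda_hat = (d^2 - R)/HPfH' (prequential: an event only uses factors
    # estimated from earlier events). It deflates the gain in seasons whose
    # forecasts are conditionally better than the climatological ensemble
    # spread suggests, and inflates it when innovations run large. The
    # bounds keep the analysis variance-contracting. None disables it.
    adaptive_spread: tuple[float, float] | None = None
    # exponential forgetting factor for the lambda update; None uses the
    # cumulative prequential mean (weight 1/(2 + #past events)), which is
    # the stabler choice for the short 7-8 event records of this study
    adaptive_spread_forgetting: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        if self.ensemble_size < 2:
            raise ValueError("ensemble_size must be at least 2")
        if any(v < 0 for v in self.obs_rel_error.values()):
            raise ValueError("observation relative errors must be >= 0")


@dataclass
class AssimilationResult:
    """Ensemble trajectories, per-event diagnostics and yield statistics."""

    scheme: Scheme
    daily: pd.DataFrame  # date, lai_mean, lai_sd, sm_mean, sm_sd, dvs_mean
    events: pd.DataFrame  # event,date,variable,prior_mean,prior_var,gain,...
    member_yields: np.ndarray
    yield_mean: float
    yield_sd: float
    yield_median: float = 0.0

    def to_json_dict(self) -> dict:
        return {"scheme": self.scheme.value,
                "yield_mean": self.yield_mean,
                "yield_sd": self.yield_sd,
                "n_events": int(self.events["event"].nunique())
                if len(self.events) else 0}


# ---------------------------------------------------------------------------
# ensemble construction


def perturb_parameters(crop: CropParams, soil: SoilParams,
                       perturbations: Sequence[PerturbationSpec],
                       rng) -> tuple[CropParams, SoilParams]:
    """One Gaussian draw of the perturbed targets, value ~ N(base, (sd*base)^2).

    Redraws (up to 100 times) until the draw is positive and keeps the
    retention ordering SMW < SMFCF < SM0 and WAV within the bucket. Raises
    when the perturbation spec is too wide to satisfy the constraints.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    for _ in range(100):
        crop_over: dict[str, float] = {}
        soil_over: dict[str, float] = {}
        for spec in perturbations:
            base = getattr(crop if spec.target in _CROP_TARGETS else soil,
                           spec.target)
            value = base * (1.0 + spec.relative_sd * rng.standard_normal())
            (crop_over if spec.target in _CROP_TARGETS else soil_over)[
                spec.target] = value
        try:
            new_crop = dataclasses.replace(crop, **crop_over) if crop_over else crop
            soil_try = dict(soil_over)
            if "WAV" in soil_try or {"SMFCF", "SM0"} & soil_try.keys():
                # keep WAV inside the (possibly narrower) perturbed bucket
                trial = dataclasses.replace(
                    soil, **{k: v for k, v in soil_try.items() if k != "WAV"})
                wav = soil_try.get("WAV", soil.WAV)
                soil_try["WAV"] = min(max(wav, 0.0),
                                      (trial.SM0 - trial.SMW) * trial.RD)
            new_soil = dataclasses.replace(soil, **soil_try) if soil_try else soil
        except ValueError:
            continue
        return new_crop, new_soil
    raise ValueError("perturbation spec too wide: 100 redraws failed the "
                     "parameter constraints")


def build_ensemble(base_crop: CropParams, base_soil: SoilParams,
                   config: SchemeConfig, rng=None
                   ) -> list[tuple[CropParams, SoilParams, CropState]]:
    """Ne perturbed members with their initial states (seeded, reproducible)."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    members = []
    for _ in range(config.ensemble_size):
        crop, soil = perturb_parameters(base_crop, base_soil,
                                        config.perturbations, rng)
        members.append((crop, soil, initial_state(crop, soil)))
    return members


def observation_variance(rec: ObservationRecord) -> float:
    """Observation-error variance from the relative-error rule: (rel*value)^2."""
    return (rec.rel_error * rec.value) ** 2


def reconcile_state(state: CropState, updated: enkf.StateVector,
                    crop: CropParams, soil: SoilParams) -> CropState:
    """Push an analysed (LAI, SM) pair back into the full crop state.

    SM is clamped to the member's [SMW, SM0]; LAI is clamped at zero and
    the leaf cohorts rescaled multiplicatively so lai == sum(w_i * sla_i)
    again, with wlv and tagp adjusted consistently. If the member had no
    leaves and the analysis created some, one fresh cohort is born at the
    current SLATB(dvs).
    """
    if tuple(updated.labels) != STATE_LABELS:
        raise ValueError(f"expected labels {STATE_LABELS}, got {updated.labels}")
    lai_new = max(0.0, float(updated.values[0]))
    sm_new = min(max(float(updated.values[1]), soil.SMW), soil.SM0)
    new = state.copy()
    new.sm = sm_new
    lai_old = state.lai
    if lai_new == lai_old:
        return new
    if lai_old > 0.0:
        ratio = lai_new / lai_old
        new.leaf_w = state.leaf_w * ratio
        new.lai = float(new.leaf_w @ state.leaf_sla) if new.leaf_w.size else 0.0
        new.wlv = state.wlv * ratio
    elif lai_new > 0.0:
        sla = crop.SLATB(state.dvs)
        if sla <= 0:
            return new
        w = lai_new / sla
        new.leaf_w = np.array([w])
        new.leaf_age = np.array([0.0])
        new.leaf_sla = np.array([sla])
        new.lai = lai_new
        new.wlv = state.wlv + w
    new.tagp = new.wlv + new.wst + new.wso
    return new


# ---------------------------------------------------------------------------
# the day loop


def _filter_records(records: Sequence[ObservationRecord],
                    scheme: Scheme) -> list[ObservationRecord]:
    keep = scheme.observed_variables
    return [r for r in records if r.variable in keep]


def run_scheme(config: SchemeConfig, crop: CropParams, soil: SoilParams,
               weather: Sequence[WeatherDay],
               observations: Sequence[ObservationRecord] = ()
               ) -> AssimilationResult:
    """Run one scheme over the season.

    The ensemble is propagated day by day; observations matching the
    scheme are assimilated end-of-day (records sharing a date form one
    stacked observation vector with diagonal R). OPEN_LOOP performs no
    analyses and differs from DA runs only by the skipped updates.
    """
    weather = list(weather)
    if not weather:
        raise ValueError("empty weather series")
    dates = {wd.date for wd in weather}
    records = _filter_records(observations, config.scheme)
    for r in records:
        if r.date not in dates:
            raise ValueError(f"observation on {r.date} outside weather window")
    by_date: dict[dt.date, list[ObservationRecord]] = {}
    for r in sorted(records, key=lambda r: (r.date, r.variable)):
        by_date.setdefault(r.date, []).append(r)

    rng_build = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    rng_obs = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    rng_forcing = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)))

    members = build_ensemble(crop, soil, config, rng_build)
    params = [(c, s) for c, s, _ in members]
    states = [st for _, _, st in members]
    ne = config.ensemble_size

    # per-member weather: water inputs carry the forcing uncertainty
    member_weather: dict[dt.date, list[WeatherDay]] = {}
    for wd in weather:
        irr = rain = None
        if config.irrigation_forcing_sd > 0 and wd.irrigation > 0:
            lo, hi = config.irrigation_forcing_bounds
            irr = wd.irrigation * np.clip(
                1.0 + config.irrigation_forcing_sd
                * rng_forcing.standard_normal(ne), lo, hi)
        if config.rain_forcing_sd > 0 and wd.rain > 0:
            s = config.rain_forcing_sd
            rain = wd.rain * np.exp(s * rng_forcing.standard_normal(ne)
                                    - 0.5 * s * s)
        if irr is not None or rain is not None:
            member_weather[wd.date] = [
                dataclasses.replace(
                    wd,
                    irrigation=float(irr[m]) if irr is not None else wd.irrigation,
                    rain=float(rain[m]) if rain is not None else wd.rain)
                for m in range(ne)]

    n = len(weather)
    lai_mean = np.empty(n); lai_sd = np.empty(n)
    sm_mean = np.empty(n); sm_sd = np.empty(n)
    dvs_mean = np.empty(n)
    event_rows: list[dict] = []
    event_no = 0
    spread_lambda = {v: 1.0 for v in STATE_LABELS}
    spread_events = {v: 0 for v in STATE_LABELS}

    for i, wd in enumerate(weather):
        wds = member_weather.get(wd.date)
        if wds is None:
            states = [advance_day(st, c, s, wd)
                      for st, (c, s) in zip(states, params)]
        else:
            states = [advance_day(st, c, s, w_m)
                      for st, (c, s), w_m in zip(states, params, wds)]
        recs = by_date.get(wd.date)
        if recs:
            data = np.array([[st.lai, st.sm] for st in states])
            ens = enkf.EnsembleMatrix(data, STATE_LABELS)
            prior_mean, prior_cov = enkf.ensemble_stats(ens)
            if config.variance_reference == "max_forecast":
                refs = [max(r.value,
                            prior_mean.values[STATE_LABELS.index(r.variable)])
                        for r in recs]
            else:
                refs = [r.value for r in recs]
            r_all = np.array([max((rec.rel_error * ref) ** 2,
                                  config.variance_floor)
                              for rec, ref in zip(recs, refs)])
            if config.qc_innovation_sd is not None:
                keep = []
                for j, rec in enumerate(recs):
                    k = STATE_LABELS.index(rec.variable)
                    s = prior_cov[k, k] + r_all[j]
                    keep.append((rec.value - prior_mean.values[k]) ** 2
                                <= config.qc_innovation_sd ** 2 * s)
                recs = [r for r, kp in zip(recs, keep) if kp]
                r_all = r_all[np.array(keep, dtype=bool)]
        if recs:
            labels = tuple(r.variable for r in recs)
            values = np.array([r.value for r in recs])
            r_diag = r_all
            obs = enkf.ObservationVector(values, labels, r_diag)
            h = enkf.selection_matrix(STATE_LABELS, labels)
            mask = None
            if config.localize_cross_updates:
                mask = np.array([[1.0 if sl == ol else 0.0 for ol in labels]
                                 for sl in STATE_LABELS])
            if config.adaptive_spread is not None:
                d_scale = np.sqrt([spread_lambda[v] for v in STATE_LABELS])
                pf_used = prior_cov * np.outer(d_scale, d_scale)
            else:
                pf_used = prior_cov
            gain = enkf.kalman_gain(pf_used, h, np.diag(r_diag))
            if mask is not None:
                gain = gain * mask
            hx = ens.data @ h.T
            if config.perturbation_mode == "second_order":
                v_pert = enkf._second_order_sample(
                    rng_obs, ne, np.diag(r_diag), decorrelate=hx)
                y_pert = values + v_pert
            else:
                y_pert = enkf.perturb_observations(obs, ne, rng_obs)
            post = enkf.EnsembleMatrix(ens.data + (y_pert - hx) @ gain.T,
                                       STATE_LABELS)
            post_mean, post_cov = enkf.ensemble_stats(post)
            if config.adaptive_spread is not None:
                lo, hi = config.adaptive_spread
                for j, rec in enumerate(recs):
                    k = STATE_LABELS.index(rec.variable)
                    pf_kk = prior_cov[k, k]
                    if pf_kk > 0:
                        d = values[j] - prior_mean.values[k]
                        lam_hat = np.clip((d * d - r_diag[j]) / pf_kk, lo, hi)
                        if config.adaptive_spread_forgetting is None:
                            spread_events[rec.variable] += 1
                            alpha = 1.0 / (2.0 + spread_events[rec.variable])
                        else:
                            alpha = config.adaptive_spread_forgetting
                        spread_lambda[rec.variable] = float(np.clip(
                            (1 - alpha) * spread_lambda[rec.variable]
                            + alpha * lam_hat, lo, hi))
            for j, rec in enumerate(recs):
                k = STATE_LABELS.index(rec.variable)
                event_rows.append({
                    "event": event_no, "date": wd.date,
                    "variable": rec.variable, "observed": rec.value,
                    "prior_mean": prior_mean.values[k],
                    "prior_var": prior_cov[k, k],
                    "gain": gain[k, j],
                    "post_mean": post_mean.values[k],
                    "post_var": post_cov[k, k]})
            states = [reconcile_state(st, enkf.StateVector(row, STATE_LABELS),
                                      c, s)
                      for st, row, (c, s) in zip(states, post.data, params)]
            event_no += 1
        lai_vals = np.fromiter((st.lai for st in states), float, ne)
        sm_vals = np.fromiter((st.sm for st in states), float, ne)
        lai_mean[i] = lai_vals.mean(); lai_sd[i] = lai_vals.std(ddof=1)
        sm_mean[i] = sm_vals.mean(); sm_sd[i] = sm_vals.std(ddof=1)
        dvs_mean[i] = sum(st.dvs for st in states) / ne

    yields = np.array([st.wso for st in states])
    daily = pd.DataFrame({"date": [wd.date for wd in weather],
                          "lai_mean": lai_mean, "lai_sd": lai_sd,
                          "sm_mean": sm_mean, "sm_sd": sm_sd,
                          "dvs_mean": dvs_mean})
    events = pd.DataFrame(event_rows, columns=[
        "event", "date", "variable", "observed", "prior_mean", "prior_var",
        "gain", "post_mean", "post_var"])
    return AssimilationResult(scheme=config.scheme, daily=daily,
                              events=events, member_yields=yields,
                              yield_mean=float(yields.mean()),
                              yield_sd=float(yields.std(ddof=1)),
                              yield_median=float(np.median(yields)))


def run_all_schemes(base_config: SchemeConfig, crop: CropParams,
                    soil: SoilParams, weather: Sequence[WeatherDay],
                    observations: Sequence[ObservationRecord],
                    schemes: Sequence[Scheme] = tuple(Scheme)
                    ) -> dict[Scheme, AssimilationResult]:
    """All requested schemes under identical conditions (same seed/ensemble)."""
    out = {}
    for scheme in schemes:
        cfg = dataclasses.replace(base_config, scheme=Scheme(scheme))
        out[Scheme(scheme)] = run_scheme(cfg, crop, soil, weather, observations)
    return out
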
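"""Unit and property tests for the daily crop growth simulator."""

import dataclasses
import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatda.crop_model import (CropParams, CropState, SoilParams, WeatherDay,
                                advance_day, daily_growth, default_crop_params,
                                default_soil_params, initial_state,
                                run_season, update_leaves, update_phenology,
                                update_soil_water)
from wheatda.synthetic_data import default_climate, generate_weather

from conftest import constant_weather


def make_day(tmin=10.0, tmax=20.0, rain=0.0, irrigation=0.0, radiation=15.0):
    return WeatherDay(date=dt.date(2017, 4, 1), tmin=tmin, tmax=tmax,
                      rain=rain, irrigation=irrigation, radiation=radiation)


class TestWeatherDay:
    def test_rejects_inverted_temperatures(self):
        with pytest.raises(ValueError):
            make_day(tmin=15.0, tmax=10.0)

    def test_rejects_negative_rain(self):
        with pytest.raises(ValueError):
            make_day(rain=-1.0)


class TestPhenology:
    def test_no_development_at_base_temperature(self, crop, soil):
        state = initial_state(crop, soil)
        wd = make_day(tmin=crop.TBASEM - 5.0, tmax=crop.TBASEM + 5.0)
        new = update_phenology(state, crop, wd)
        assert new.dvs == state.dvs
        assert new.tsum == state.tsum

    def test_anthesis_after_tsum1_days(self, soil):
        # constant mean temperature of 20 degC and TSUM1 = 1000 degC d:
        # anthesis (DVS = 1) must be reached on day 50
        crop = default_crop_params(TSUM1=1000.0, TSUM2=900.0, TBASEM=0.0)
        state = initial_state(crop, soil)
        wd = make_day(tmin=15.0, tmax=25.0)  # mean 20
        days_to_anthesis = None
        for day in range(1, 120):
            state = update_phenology(state, crop, wd)
            if state.dvs >= 1.0 and days_to_anthesis is None:
                days_to_anthesis = day
        assert days_to_anthesis == 50

    def test_dvs_monotone_and_capped_at_maturity(self, crop, soil):
        state = initial_state(crop, soil)
        wd = make_day(tmin=20.0, tmax=30.0)
        prev = 0.0
        for _ in range(400):
            state = update_phenology(state, crop, wd)
            assert state.dvs >= prev
            prev = state.dvs
        assert state.dvs == 2.0


class TestLeafDynamics:
    def test_senescent_cohort_removed(self, crop):
        sla = 0.002
        state = CropState(dvs=0.8, leaf_w=np.array([100.0, 50.0]),
                          leaf_age=np.array([crop.SPAN + 0.1, 5.0]),
                          leaf_sla=np.array([sla, sla]),
                          lai=150.0 * sla, wlv=150.0, sm=0.25)
        new = update_leaves(state, crop, make_day(), 0.0)
        assert new.leaf_w.size == 1
        assert new.wlv == pytest.approx(50.0)
        assert new.lai == pytest.approx(state.lai - 100.0 * sla)

    def test_no_ageing_at_or_below_tbase(self, crop):
        state = CropState(dvs=0.8, leaf_w=np.array([50.0]),
                          leaf_age=np.array([10.0]),
                          leaf_sla=np.array([0.002]), lai=0.1, wlv=50.0,
                          sm=0.25)
        cold = make_day(tmin=crop.TBASE - 6.0, tmax=crop.TBASE + 2.0)
        new = update_leaves(state, crop, cold, 0.0)
        assert new.leaf_age[0] == pytest.approx(10.0)

    def test_leaf_at_35_degrees_lives_span_days(self, soil):
        crop = default_crop_params(SPAN=20.0, TBASE=0.0)
        state = CropState(dvs=0.8, leaf_w=np.array([50.0]),
                          leaf_age=np.array([0.0]),
                          leaf_sla=np.array([0.002]), lai=0.1, wlv=50.0,
                          sm=0.25)
        hot = make_day(tmin=35.0, tmax=35.0)
        for day in range(1, 25):
            state = update_leaves(state, crop, hot, 0.0)
            if state.leaf_w.size == 0:
                break
        # ages one physiological day per calendar day at 35 degC; removal
        # happens on the first day age exceeds SPAN
        assert day == 21

    def test_juvenile_exponential_cap(self, soil):
        # lai = 0.1 and RGRLAI * dTeff = 0.05 caps growth at lai*e^0.05
        crop = default_crop_params(RGRLAI=0.005, TBASE=0.0)
        sla = crop.SLATB(0.0)
        state = CropState(dvs=0.1, leaf_w=np.array([0.1 / sla]),
                          leaf_age=np.array([1.0]),
                          leaf_sla=np.array([sla]), lai=0.1,
                          wlv=0.1 / sla, sm=0.25)
        wd = make_day(tmin=5.0, tmax=15.0)  # mean 10 -> dTeff = 10
        new = update_leaves(state, crop, wd, new_leaf_dw=1e6)
        assert new.lai <= 0.1 * math.exp(0.05) + 1e-12
        assert new.lai == pytest.approx(0.1 * math.exp(0.05))

    def test_negative_leaf_growth_rejected(self, crop):
        state = CropState(sm=0.25)
        with pytest.raises(ValueError):
            update_leaves(state, crop, make_day(), -1.0)


class TestSoilWater:
    def test_zero_flux_leaves_moisture_unchanged(self, soil):
        state = CropState(sm=0.25)
        new, fx = update_soil_water(state, soil, make_day(), 0.0, 0.0)
        assert new.sm == pytest.approx(0.25)
        assert fx.residual == pytest.approx(0.0, abs=1e-12)

    def test_saturating_rain_produces_runoff(self, soil):
        state = CropState(sm=soil.SMFCF)
        deluge = make_day(rain=400.0)  # 40 cm on a 60 cm bucket
        new, fx = update_soil_water(state, soil, deluge, 0.0, 0.0)
        assert new.sm == pytest.approx(soil.SM0)
        assert fx.runoff > 0.0

    def test_extraction_cannot_pass_wilting_point(self, soil):
        state = CropState(sm=soil.SMW + 0.01)
        new, fx = update_soil_water(state, soil, make_day(), 5.0, 5.0)
        assert new.sm >= soil.SMW - 1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(sm=st.floats(0.12, 0.46), rain=st.floats(0, 80),
           irr=st.floats(0, 80), e=st.floats(0, 1.0), t=st.floats(0, 1.0))
    def test_water_balance_closes(self, sm, rain, irr, e, t):
        soil = default_soil_params()
        state = CropState(sm=min(max(sm, soil.SMW), soil.SM0))
        wd = make_day(rain=rain, irrigation=irr)
        new, fx = update_soil_water(state, soil, wd, e, t)
        assert abs(fx.residual) < 1e-9
        assert soil.SMW <= new.sm <= soil.SM0


class TestDailyGrowth:
    def test_no_canopy_no_growth(self, crop, mild_day):
        state = CropState(lai=0.0, wlv=0.0, sm=0.25)
        new, leaf = daily_growth(state, crop, mild_day, 1.0)
        assert leaf == 0.0
        assert new.tagp == pytest.approx(state.tagp)

    def test_full_stress_stops_growth(self, crop, mild_day):
        state = CropState(lai=2.0, wlv=500.0, sm=0.25)
        new, leaf = daily_growth(state, crop, mild_day, 0.0)
        assert leaf == 0.0
        assert new.wso == state.wso

    def test_growth_stops_at_maturity(self, crop, mild_day):
        state = CropState(dvs=2.0, lai=2.0, wlv=500.0, sm=0.25)
        new, leaf = daily_growth(state, crop, mild_day, 1.0)
        assert leaf == 0.0
        assert new.wrt == state.wrt

    def test_storage_organs_never_shrink(self, crop, soil, season_weather):
        res = run_season(crop, soil, season_weather)
        wso = res.trajectory["wso"].to_numpy()
        assert np.all(np.diff(wso) >= -1e-12)


class TestAdvanceDay:
    def test_deterministic(self, crop, soil, mild_day):
        a = advance_day(initial_state(crop, soil), crop, soil, mild_day)
        b = advance_day(initial_state(crop, soil), crop, soil, mild_day)
        assert a.lai == b.lai and a.sm == b.sm and a.tsum == b.tsum
        assert np.array_equal(a.leaf_w, b.leaf_w)

    def test_mass_consistency_all_season(self, crop, soil, season_weather):
        state = initial_state(crop, soil)
        for wd in season_weather:
            state = advance_day(state, crop, soil, wd)
            assert state.tagp == pytest.approx(
                state.wlv + state.wst + state.wso, rel=1e-9)
            assert min(state.wlv, state.wst, state.wso, state.wrt) >= 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_irrigation_never_reduces_yield(self, crop, soil, seed):
        climate = default_climate(2017)
        weather = generate_weather(climate, dt.date(2016, 10, 10), 249, seed)
        dry = [dataclasses.replace(wd, irrigation=0.0) for wd in weather]
        y_wet = run_season(crop, soil, weather).yield_kg_ha
        y_dry = run_season(crop, soil, dry).yield_kg_ha
        assert y_wet >= y_dry - 1e-9


class TestRunSeason:
    def test_no_seed_biomass_no_growth(self, soil, season_weather):
        crop = default_crop_params()
        crop = dataclasses.replace(crop, TDWI=1e-12)
        res = run_season(crop, soil, season_weather)
        assert res.trajectory["lai"].max() < 1e-6
        assert res.yield_kg_ha < 1e-6

    def test_initial_moisture_from_available_water(self, crop):
        soil = default_soil_params()
        soil = dataclasses.replace(
            soil, WAV=(soil.SMFCF - soil.SMW) * soil.RD)
        state = initial_state(crop, soil)
        assert state.sm == pytest.approx(soil.SMFCF)

    def test_moisture_always_in_physical_range(self, crop, soil,
                                               season_weather):
        res = run_season(crop, soil, season_weather)
        sm = res.trajectory["sm"]
        assert (sm >= soil.SMW - 1e-12).all()
        assert (sm <= soil.SM0 + 1e-12).all()

    def test_trajectory_covers_every_day(self, crop, soil, season_weather):
        res = run_season(crop, soil, season_weather)
        assert len(res.trajectory) == len(season_weather)

    def test_sowing_day_outside_weather_errors(self, crop, soil,
                                               season_weather):
        with pytest.raises(ValueError):
            run_season(crop, soil, season_weather,
                       sowing_day=dt.date(2020, 1, 1))

    def test_season_water_balance_closes(self, crop, soil, season_weather):
        res = run_season(crop, soil, season_weather, collect_fluxes=True)
        total_in = sum(f.rain + f.irrigation for f in res.fluxes)
        total_out = sum(f.evaporation + f.transpiration + f.percolation
                        + f.runoff for f in res.fluxes)
        delta = sum(f.delta_w for f in res.fluxes)
        assert abs(total_in - total_out - delta) < 1e-6


class TestParameterValidation:
    def test_partition_tables_must_sum_to_one(self):
        with pytest.raises(ValueError):
            default_crop_params(FLTB=[[0.0, 0.9], [2.0, 0.9]])

    def test_retention_ordering_enforced(self):
        with pytest.raises(ValueError):
            SoilParams(SM0=0.3, SMFCF=0.35, SMW=0.1)

    def test_wav_bounded_by_bucket(self):
        with pytest.raises(ValueError):
            SoilParams(WAV=100.0)
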
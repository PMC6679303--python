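import datetime as dt

import numpy as np
import pytest

from wheatda.crop_model import (WeatherDay, default_crop_params,
                                default_soil_params)
from wheatda.synthetic_data import default_climate, generate_weather


@pytest.fixture(scope="session")
def crop():
    return default_crop_params()


@pytest.fixture(scope="session")
def soil():
    return default_soil_params()


@pytest.fixture(scope="session")
def season_weather():
    """One deterministic synthetic season, sowing to mid-June."""
    return generate_weather(default_climate(2017), dt.date(2016, 10, 10),
                            249, seed=1234)


def constant_weather(n_days, tmin=10.0, tmax=20.0, rain=0.0, irrigation=0.0,
                     radiation=15.0, start=dt.date(2017, 3, 1)):
    return [WeatherDay(date=start + dt.timedelta(days=i), tmin=tmin,
                       tmax=tmax, rain=rain, irrigation=irrigation,
                       radiation=radiation) for i in range(n_days)]


@pytest.fixture
def mild_day():
    return WeatherDay(date=dt.date(2017, 4, 1), tmin=10.0, tmax=20.0,
                      rain=0.0, irrigation=0.0, radiation=18.0)
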
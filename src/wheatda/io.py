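"""CSV/JSON/YAML interchange for weather, observations and parameters."""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .crop_model import CropParams, PiecewiseTable, SoilParams, WeatherDay
from .synthetic_data import ObservationRecord, angstrom_radiation

__all__ = [
    "read_weather_csv",
    "write_weather_csv",
    "read_observations_csv",
    "write_observations_csv",
    "read_params",
    "write_params",
]

_WEATHER_COLUMNS = ["date", "tmin", "tmax", "rain", "irrigation",
                    "sunshine_hours", "radiation", "wind"]


def read_weather_csv(path, latitude: float | None = None,
                     angstrom_a: float = 0.25,
                     angstrom_b: float = 0.50) -> list[WeatherDay]:
    """Read the weather dialect ``date,tmin,tmax,rain,irrigation,
    sunshine_hours,radiation,wind``.

    Rows may give either radiation directly or sunshine hours, in which
    case ``latitude`` is required and the Angstrom conversion is applied.
    """
    df = pd.read_csv(path)
    missing = {"date", "tmin", "tmax", "rain"} - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        date = dt.date.fromisoformat(str(row.date))
        rad = getattr(row, "radiation", None)
        if rad is None or pd.isna(rad):
            sun = getattr(row, "sunshine_hours", None)
            if sun is None or pd.isna(sun):
                raise ValueError(
                    f"{date}: need sunshine_hours or radiation")
            if latitude is None:
                raise ValueError("latitude required to convert sunshine hours")
            rad = angstrom_radiation(float(sun), latitude,
                                     date.timetuple().tm_yday,
                                     angstrom_a, angstrom_b)
        irr = getattr(row, "irrigation", 0.0)
        wind = getattr(row, "wind", None)
        out.append(WeatherDay(
            date=date, tmin=float(row.tmin), tmax=float(row.tmax),
            rain=float(row.rain),
            irrigation=0.0 if pd.isna(irr) else float(irr),
            radiation=float(rad),
            wind=None if wind is None or pd.isna(wind) else float(wind)))
    return out


def write_weather_csv(weather: Sequence[WeatherDay], path) -> None:
    rows = [{"date": wd.date.isoformat(), "tmin": wd.tmin, "tmax": wd.tmax,
             "rain": wd.rain, "irrigation": wd.irrigation,
             "sunshine_hours": "", "radiation": wd.radiation,
             "wind": "" if wd.wind is None else wd.wind} for wd in weather]
    pd.DataFrame(rows, columns=_WEATHER_COLUMNS).to_csv(path, index=False)


def read_observations_csv(path, default_rel_errors=None
                          ) -> list[ObservationRecord]:
    """Read ``date,variable,value,rel_error`` (rel_error optional)."""
    default_rel_errors = default_rel_errors or {"LAI": 0.10, "SM": 0.35}
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        rel = getattr(row, "rel_error", None)
        var = str(row.variable)
        if rel is None or pd.isna(rel):
            rel = default_rel_errors.get(var, 0.0)
        out.append(ObservationRecord(
            date=dt.date.fromisoformat(str(row.date)), variable=var,
            value=float(row.value), rel_error=float(rel)))
    return out


def write_observations_csv(records: Sequence[ObservationRecord], path) -> None:
    pd.DataFrame([{"date": r.date.isoformat(), "variable": r.variable,
                   "value": r.value, "rel_error": r.rel_error}
                  for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# parameter files


def _params_to_dict(crop: CropParams, soil: SoilParams) -> dict:
    crop_d = {}
    for f in dataclasses.fields(crop):
        v = getattr(crop, f.name)
        crop_d[f.name] = v.to_knots() if isinstance(v, PiecewiseTable) else v
    return {"crop": crop_d, "soil": dataclasses.asdict(soil)}


def write_params(crop: CropParams, soil: SoilParams, path) -> None:
    path = Path(path)
    payload = _params_to_dict(crop, soil)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_params(path) -> tuple[CropParams, SoilParams]:
    path = Path(path)
    text = path.read_text()
    payload = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
               else json.loads(text))
    return CropParams(**payload.get("crop", {})), SoilParams(**payload.get("soil", {}))
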
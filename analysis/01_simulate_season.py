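"""Open-loop baseline: one synthetic season of the winter wheat model.

Generates a season of semi-humid weather (dry winter, five flood
irrigations), runs the water-limited crop model with the calibrated
defaults, and writes the weather series and the daily trajectory
(DVS, LAI, SM, biomass, grain) under results/.
"""

import argparse
from pathlib import Path

import wheatda as w
from wheatda.io import write_weather_csv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/01_season"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    weather = w.study.default_season(args.seed)
    crop = w.default_crop_params()
    soil = w.default_soil_params()
    res = w.run_season(crop, soil, weather, collect_fluxes=True)

    write_weather_csv(weather, args.out / "weather.csv")
    res.to_csv(args.out / "trajectory.csv")

    tr = res.trajectory
    rain = sum(wd.rain for wd in weather)
    irr = sum(wd.irrigation for wd in weather)
    residual = sum(f.residual for f in res.fluxes)
    print(f"season {weather[0].date} .. {weather[-1].date} "
          f"({len(weather)} days), seed {args.seed}")
    print(f"  rain {rain:.0f} mm, irrigation {irr:.0f} mm")
    print(f"  peak LAI {tr['lai'].max():.2f}, "
          f"maturity day {res.maturity_day}, "
          f"grain yield {res.yield_kg_ha:.0f} kg/ha")
    print(f"  water balance residual {residual:.2e} cm")
    print(f"wrote {args.out}/weather.csv and trajectory.csv")


if __name__ == "__main__":
    main()
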
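"""Regional experiment: wheat-fraction masking and spatial variability.

Builds a synthetic 20x20 grid of 1 km-style cells with uniform wheat
fractions and per-cell truth jitter, simulates only the cells whose wheat
fraction exceeds 40%, and contrasts the spatial yield variability of the
open-loop (cell-invariant inputs, hence none) with the joint-assimilation
run (per-cell observations re-introduce it).
"""

import argparse
from pathlib import Path

import numpy as np

import wheatda as w
from wheatda.assimilation import Scheme, SchemeConfig
from wheatda.evaluation import regional_run
from wheatda.synthetic_data import (RegionalGridSpec,
                                    default_observation_plan,
                                    generate_region)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--ensemble-size", type=int, default=20)
    ap.add_argument("--out", type=Path, default=Path("results/04_regional"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    crop = w.default_crop_params()
    soil = w.default_soil_params()
    weather = w.study.default_season(args.seed)
    plan = default_observation_plan(2017)
    spec = RegionalGridSpec(n_rows=20, n_cols=20)
    cells = generate_region(spec, crop, soil, weather, plan, seed=args.seed)

    results = {}
    for scheme in (Scheme.OPEN_LOOP, Scheme.DA_JOINT):
        cfg = SchemeConfig(scheme=scheme, ensemble_size=args.ensemble_size,
                           seed=args.seed)
        table, summary = regional_run(cells, cfg, crop, soil, weather)
        table.to_csv(args.out / f"cells_{scheme.value}.csv", index=False)
        results[scheme.value] = summary

    n_inc = results["open_loop"]["n_included"]
    print(f"grid {spec.n_rows}x{spec.n_cols}, threshold "
          f"{spec.threshold:.0%}: {n_inc} of "
          f"{spec.n_rows * spec.n_cols} cells simulated")
    for name, s in results.items():
        print(f"  {name:>9}: mean yield {s['yield_mean']:7.0f} kg/ha, "
              f"spatial sd {np.sqrt(s['yield_var']):6.0f} kg/ha "
              f"(CV {s['yield_cv']:.3f})")
    print("assimilation adds the spatial variability the cell-invariant "
          "open-loop cannot express")
    print(f"wrote per-cell tables to {args.out}/")


if __name__ == "__main__":
    main()
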
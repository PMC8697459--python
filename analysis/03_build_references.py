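#!/usr/bin/env python
"""Construct all growth-reference tables and charts.

Builds sex-specific stature-, weight- and head-circumference-for-age
references (0-18 y; HC 0-5 y) and weight-for-height references over
the sex-specific height domains, then reports how far the recovered
median curves sit from the generator's truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from growthref import (
    BuilderConfig, CurveSpec, build_curve, build_reference_table,
    build_weight_for_height, pair_weight_height, read_cohort,
    select_for_curve, write_reference_table,
)
from growthref.charts import plot_reference

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(BASE / "cleaned" / "cohort.csv",
                         BASE / "cleaned" / "events.csv")
    out = BASE / "references"
    out.mkdir(parents=True, exist_ok=True)
    cfg = BuilderConfig()

    weight_points = {}
    for sex in ("male", "female"):
        for measure, hi in (("stature", 216), ("weight", 216),
                            ("head_circumference", 60)):
            spec = CurveSpec(sex, measure, age_domain=(0, hi))
            res = build_curve(cohort, spec, cfg)
            name = f"{sex}_{measure}"
            write_reference_table(res["table"], out / f"ref_{name}.csv")
            plot_reference(res["table"], out / f"chart_{name}.png")
            c = res["counts"]
            extra = (f", {c.get('extreme_weight_excluded', 0)} beyond 3 SD"
                     if measure == "weight" else "")
            print(f"{name}: {c['eligible']} eligible points{extra}")
            if measure == "weight":
                weight_points[sex] = res["points"]

    for sex in ("male", "female"):
        lo, hi = cfg.height_domains[sex]
        spec = CurveSpec(sex, "weight", index_kind="height_cm", age_domain=(lo, hi))
        el_s = select_for_curve(cohort, CurveSpec(sex, "stature", age_domain=(0, 300)))
        paired = pair_weight_height(pd.concat(
            [el_s.points, weight_points[sex]], ignore_index=True))
        cs, sd_pair, _ = build_weight_for_height(paired, spec, cfg)
        table = build_reference_table(cs, sd_pair, spec)
        write_reference_table(table, out / f"ref_{sex}_weight_for_height.csv")
        plot_reference(table, out / f"chart_{sex}_weight_for_height.png")
        print(f"{sex} weight-for-height: {len(paired)} pairs over "
              f"[{lo:g}, {hi:g}] cm")


if __name__ == "__main__":
    main()
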
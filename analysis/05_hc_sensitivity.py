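#!/usr/bin/env python
"""Head-circumference neurosurgery sensitivity analysis.

Rebuilds the head-circumference-for-age curves with and without points
recorded after cervicomedullary decompression or shunt placement and
reports the maximum per-percentile difference over the grid.
"""

from pathlib import Path

from growthref import CurveSpec, read_cohort, sensitivity_compare

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(BASE / "cleaned" / "cohort.csv",
                         BASE / "cleaned" / "events.csv")
    for sex in ("male", "female"):
        spec = CurveSpec(sex, "head_circumference", age_domain=(0, 60))
        _, _, diffs = sensitivity_compare(cohort, spec)
        report = ", ".join(f"{lvl}: {d:.3f} cm" for lvl, d in diffs.items())
        print(f"{sex}: max |with - without| per percentile -> {report}")


if __name__ == "__main__":
    main()
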
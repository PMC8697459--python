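#!/usr/bin/env python
"""Apply the plausibility screens and <15-day averaging.

Flags implausible values and jumps, drops them (the automated stand-in
for chart review), collapses near-duplicate visits, and writes the
cleaned cohort plus the flag and audit ledgers.
"""

from pathlib import Path

from growthref import (
    average_close_measurements, flag_errors, flags_to_frame, read_cohort,
    resolve_flags, write_cohort,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(BASE / "cohort" / "cohort.csv",
                         BASE / "cohort" / "events.csv")
    out = BASE / "cleaned"
    out.mkdir(parents=True, exist_ok=True)
    flags = flag_errors(cohort)
    flags_to_frame(flags).to_csv(out / "flags.csv", index=False)
    print(f"{len(flags)} flags on {cohort.n_points()} raw points")
    cleaned, audit = resolve_flags(cohort, flags)
    audit.to_csv(out / "audit.csv", index=False)
    averaged = average_close_measurements(cleaned)
    write_cohort(averaged, out / "cohort.csv", out / "events.csv")
    print(f"{cohort.n_points()} -> {cleaned.n_points()} after drops "
          f"-> {averaged.n_points()} after <15-day averaging")


if __name__ == "__main__":
    main()
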
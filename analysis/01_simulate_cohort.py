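#!/usr/bin/env python
"""Generate the synthetic study cohort.

Draws a 1,000-subject longitudinal cohort with the study's structure
(51% male, ~12% premature, ~12% unknown gestational age, 5% treated,
18% with neurosurgical events, transcription errors at recorded
positions) and writes the cohort, events and truth-ledger CSVs.
"""

from pathlib import Path

from growthref import SimulationConfig, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(n_subjects=1000, seed=seed)
    cohort, truth = generate_cohort(cfg)
    write_cohort(cohort, OUT / "cohort.csv", OUT / "events.csv")
    truth.errors.to_csv(OUT / "truth_errors.csv", index=False)
    truth.subject_effects.to_csv(OUT / "truth_subject_effects.csv", index=False)
    print(f"{cohort.n_subjects()} subjects, {cohort.n_points()} points, "
          f"{len(truth.errors)} injected errors -> {OUT}")


if __name__ == "__main__":
    main()
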
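import numpy as np
import pandas as pd
import pytest

from growthref import (
    Cohort, SimulationConfig, average_close_measurements, flag_errors,
    generate_cohort, resolve_flags,
)


@pytest.fixture(scope="session")
def small_cohort():
    """120-subject synthetic cohort with its truth ledger."""
    return generate_cohort(SimulationConfig(n_subjects=120, seed=7))


@pytest.fixture(scope="session")
def clean_cohort(small_cohort):
    """The small cohort after cleaning and <15-day averaging."""
    cohort, _ = small_cohort
    flags = flag_errors(cohort)
    cleaned, _ = resolve_flags(cohort, flags)
    return average_close_measurements(cleaned)


def make_cohort(points_rows, subjects=None, events_rows=()):
    """Hand-built tiny cohort for rule-level tests.

    ``points_rows``: (subject_id, measure, age_days, value) tuples.
    """
    pts = pd.DataFrame(points_rows,
                       columns=["subject_id", "measure", "age_days", "value"])
    pts["position"] = None
    sids = sorted(pts["subject_id"].unique())
    if subjects is None:
        subjects = pd.DataFrame({
            "subject_id": sids, "sex": "male",
            "gestational_age_weeks": 40.0, "birth_decade": "2010s",
        })
    events = pd.DataFrame(list(events_rows),
                          columns=["subject_id", "event_kind", "age_days"])
    return Cohort(subjects, pts, events)


@pytest.fixture
def tiny_table():
    """Flat reference table: mean 10, sd_upper 2, sd_lower 1, ages 0-24 mo."""
    from growthref import ReferenceTable

    grid = np.arange(0.0, 25.0)
    data = pd.DataFrame({
        "index": grid, "mean": 10.0, "sd_upper": 2.0, "sd_lower": 1.0,
        "p5": 8.0, "p25": 9.0, "p50": 10.0, "p75": 11.0, "p95": 12.0,
    })
    return ReferenceTable("male", "weight", "age_months", data)
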
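"""Asymmetric-SD Z-scores, extreme-weight exclusion and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from growthref import (
    adult_height_summary, birth_summary, exclude_extreme_weights,
    invert_zscore, secular_summary, weight_gain_per_day, zscore, zscore_frame,
)
from growthref.errors import InsufficientDataError, RangeError
from growthref.records import DAYS_PER_MONTH


def test_zscore_formula(tiny_table):
    assert zscore(10.0, 12.0, tiny_table).z == 0.0
    assert zscore(14.0, 12.0, tiny_table).z == pytest.approx(2.0)   # upper SD 2
    assert zscore(8.0, 12.0, tiny_table).z == pytest.approx(-2.0)   # lower SD 1
    assert zscore(10.0, 12.0, tiny_table).side == "lower"  # ties to lower


def test_zscore_out_of_range(tiny_table):
    with pytest.raises(RangeError):
        zscore(10.0, 30.0, tiny_table)


def _flat_table():
    from growthref import ReferenceTable

    grid = np.arange(0.0, 25.0)
    return ReferenceTable("male", "weight", "age_months", pd.DataFrame({
        "index": grid, "mean": 10.0, "sd_upper": 2.0, "sd_lower": 1.0,
        "p5": 8.0, "p25": 9.0, "p50": 10.0, "p75": 11.0, "p95": 12.0}))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=5.0, max_value=15.0))
def test_zscore_monotone_in_value(value):
    # strictly increasing and continuous across the mean
    table = _flat_table()
    z1 = zscore(value, 12.0, table).z
    z2 = zscore(value + 0.01, 12.0, table).z
    assert z2 > z1
    near = zscore(10.0 + 1e-9, 12.0, table).z
    assert abs(near) < 1e-6


def test_zscore_roundtrip_exact(tiny_table):
    for v in (6.5, 9.99, 10.0, 10.01, 14.2):
        z = zscore(v, 7.3, tiny_table).z
        assert invert_zscore(z, 7.3, tiny_table) == pytest.approx(v, abs=1e-12)


def test_exclusion_partition(tiny_table):
    pts = pd.DataFrame({
        "subject_id": ["A", "B", "C"], "measure": "weight",
        "age_days": 12 * DAYS_PER_MONTH,
        # z = +3.5, +2.9, -3.5  (upper SD 2, lower SD 1)
        "value": [17.0, 15.8, 6.5], "position": None})
    kept, excluded = exclude_extreme_weights(pts, tiny_table, threshold=3.0)
    assert list(excluded["subject_id"]) == ["A", "C"]
    assert list(kept["subject_id"]) == ["B"]
    kept_all, none = exclude_extreme_weights(pts, tiny_table, threshold=np.inf)
    assert len(none) == 0 and len(kept_all) == 3


def test_secular_summary_single_point_and_partition(tiny_table):
    subs = pd.DataFrame({"subject_id": ["A", "B"], "sex": ["male", "male"],
                         "gestational_age_weeks": 40.0,
                         "birth_decade": ["2010s", None]})
    zs = pd.DataFrame({"subject_id": ["A", "B"], "age_days": [100.0, 200.0],
                       "z": [1.3, -0.2]})
    out = secular_summary(zs, subs)
    a = out[out["birth_decade"] == "2010s"].iloc[0]
    assert a["min"] == a["q1"] == a["median"] == a["q3"] == a["max"] == 1.3
    assert set(out["birth_decade"]) == {"2010s", "unknown"}
    assert out["n"].sum() == len(zs)


def test_weight_gain_per_day_arithmetic():
    lin = lambda m: 3.0 + 0.636 * np.asarray(m, float)  # kg per month
    out = weight_gain_per_day(lin)
    assert out[(0, 1)] == pytest.approx(636.0 / DAYS_PER_MONTH, rel=1e-9)
    flat = weight_gain_per_day(lambda m: np.asarray(m, float) * 0 + 4.0)
    assert all(v == 0.0 for v in flat.values())


def test_weight_gain_matches_finite_difference():
    curve = lambda m: 40 - 37 * np.exp(-0.015 * np.asarray(m, float))
    out = weight_gain_per_day(curve)
    for (a, b), got in out.items():
        expect = 1000 * (curve(b) - curve(a)) / ((b - a) * DAYS_PER_MONTH)
        assert got == pytest.approx(float(expect), rel=1e-12)


def test_birth_summary_closed_form():
    pts = pd.DataFrame({"age_days": [0.0, 1.0, 2.0], "value": [3.0, 4.0, 5.0]})
    out = birth_summary(pts)
    assert out["mean"] == pytest.approx(4.0)
    assert out["sd"] == pytest.approx(1.0)
    assert out["ci_low"] == pytest.approx(4 - 1.96 / np.sqrt(3))
    assert out["ci_high"] == pytest.approx(4 + 1.96 / np.sqrt(3))
    same = birth_summary(pts, comparator_mean=4.0)
    assert same["comparator_outside_ci"] is False


def test_birth_summary_needs_two_points():
    with pytest.raises(InsufficientDataError):
        birth_summary(pd.DataFrame({"age_days": [0.0], "value": [3.0]}))


def test_birth_ci_coverage():
    """~95% of normal-theory CIs should cover the true mean."""
    rng = np.random.default_rng(12)
    n, reps = 50, 2000
    draws = rng.normal(3.3, 0.4, (reps, n))
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1)
    half = 1.96 * sds / np.sqrt(n)
    cover = np.mean((means - half <= 3.3) & (3.3 <= means + half))
    assert 0.93 < cover < 0.97


def test_adult_height_summary():
    cutoff = 216 * DAYS_PER_MONTH
    pts = pd.DataFrame({
        "subject_id": ["A", "A", "B", "C"], "measure": "stature",
        "age_days": [cutoff - 100, cutoff + 10, cutoff + 30, 1000.0],
        "value": [119.0, 120.0, 130.0, 80.0], "position": None})
    subs = pd.DataFrame({"subject_id": ["A", "B", "C"], "sex": "male"})
    out = adult_height_summary(pts, subs)
    row = out[out["sex"] == "male"].iloc[0]
    assert row["n"] == 2           # C has no adult measurement
    assert row["mean"] == pytest.approx(125.0)
    assert row["sd"] == pytest.approx(np.sqrt(50.0))


def test_adult_recovery_on_synthetic(small_cohort):
    from growthref.synthetic_cohort import true_median

    cohort, truth = small_cohort
    out = adult_height_summary(cohort.points, cohort.subjects)
    for _, row in out.iterrows():
        expect = true_median(truth.config, row["sex"], "stature", 228.0)
        assert abs(row["mean"] - expect) < 3 * row["sd"] / np.sqrt(row["n"]) + 1.0


def test_zscore_frame_vectorised_matches_scalar(tiny_table):
    pts = pd.DataFrame({"subject_id": list("ABC"), "measure": "weight",
                        "age_days": np.array([3.0, 9.0, 20.0]) * DAYS_PER_MONTH,
                        "value": [9.0, 11.5, 10.0], "position": None})
    out = zscore_frame(pts, tiny_table)
    for i in range(3):
        z = zscore(pts.loc[i, "value"], pts.loc[i, "age_days"] / DAYS_PER_MONTH,
                   tiny_table)
        assert out.loc[i, "z"] == pytest.approx(z.z)
        assert out.loc[i, "side"] == z.side
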
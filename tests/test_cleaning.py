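"""The six plausibility screens, flag resolution, and <15-day averaging."""

import numpy as np
import pytest

from growthref import (
    Resolution, average_close_measurements, flag_errors, resolve_flags,
)
from growthref.errors import InvariantError

from conftest import make_cohort


def rules_of(flags):
    return sorted(f.rule_id for f in flags)


# one firing case and one just-inside-threshold silent case per rule
RULE_CASES = [
    ("stature_max", [("A", "stature", 5000, 145.0)],
                    [("A", "stature", 5000, 139.9)]),
    ("stature_jump", [("A", "stature", 100, 80.0), ("A", "stature", 200, 86.0)],
                     [("A", "stature", 100, 80.0), ("A", "stature", 200, 85.0)]),
    ("weight_max", [("A", "weight", 5000, 70.0)],
                   [("A", "weight", 5000, 69.0)]),
    ("weight_jump", [("A", "weight", 100, 30.0), ("A", "weight", 220, 36.0)],
                    [("A", "weight", 100, 30.0), ("A", "weight", 313, 36.0)]),
    ("hc_max", [("A", "head_circumference", 100, 61.0)],
               [("A", "head_circumference", 100, 60.0)]),
    ("hc_jump", [("A", "head_circumference", 100, 42.0),
                 ("A", "head_circumference", 252, 46.0)],
                [("A", "head_circumference", 100, 42.0),
                 ("A", "head_circumference", 252, 44.0)]),
]


@pytest.mark.parametrize("rule,firing,silent", RULE_CASES,
                         ids=[c[0] for c in RULE_CASES])
def test_each_rule_fires_and_stays_silent(rule, firing, silent):
    assert rules_of(flag_errors(make_cohort(firing))) == [rule]
    assert flag_errors(make_cohort(silent)) == []


def test_weight_jump_requires_under_six_months():
    # 6 kg apart: flagged at 120 days, silent at 200 days
    near = make_cohort([("A", "weight", 100, 30.0), ("A", "weight", 220, 36.0)])
    far = make_cohort([("A", "weight", 100, 30.0), ("A", "weight", 300, 36.0)])
    assert rules_of(flag_errors(near)) == ["weight_jump"]
    assert flag_errors(far) == []


def test_stature_jump_is_direction_free():
    drop = make_cohort([("A", "stature", 100, 86.0), ("A", "stature", 200, 80.0)])
    assert rules_of(flag_errors(drop)) == ["stature_jump"]


def test_flagging_is_pure_and_repeatable(small_cohort):
    cohort, _ = small_cohort
    before = cohort.points.copy()
    f1, f2 = flag_errors(cohort), flag_errors(cohort)
    assert f1 == f2
    assert cohort.points.equals(before)


def test_error_free_cohort_yields_zero_flags():
    """Plausible untreated trajectories satisfy every screen."""
    from growthref import SimulationConfig, generate_cohort

    cohort, truth = generate_cohort(SimulationConfig(
        n_subjects=150, seed=31, error_rate=0.0,
        premature_fraction=0.0, treatment_fraction=0.0))
    assert len(truth.errors) == 0
    assert flag_errors(cohort) == []


def test_resolution_drop_keep_replace():
    cohort = make_cohort([("A", "stature", 5000, 145.0),
                          ("A", "stature", 5200, 100.0)])
    flags = flag_errors(cohort)
    dropped, audit = resolve_flags(cohort, flags)
    assert dropped.n_points() < cohort.n_points()
    assert (audit["action"] == "drop").all()

    kept, audit = resolve_flags(cohort, flags,
                                {i: Resolution("keep") for i in range(len(flags))},
                                iterate_jumps=False)
    assert kept.points.equals(cohort.points)
    assert len(audit) == 0

    maxflag = [f for f in flags if f.rule_id == "stature_max"]
    repl, audit = resolve_flags(cohort, maxflag, {0: Resolution("replace", 139.0)},
                                iterate_jumps=False)
    assert (repl.points["value"] == 139.0).any()
    assert (audit["action"] == "replace").all()


def test_replacement_violating_hard_bound_refused():
    cohort = make_cohort([("A", "stature", 5000, 145.0)])
    flags = flag_errors(cohort)
    with pytest.raises(InvariantError, match="hard bound"):
        resolve_flags(cohort, flags, {0: Resolution("replace", 150.0)})


def test_hard_bound_rules_quiet_after_all_drop(small_cohort):
    cohort, _ = small_cohort
    cleaned, _ = resolve_flags(cohort, flag_errors(cohort))
    remaining = rules_of(flag_errors(cleaned))
    assert not any(r in remaining for r in ("stature_max", "weight_max", "hc_max"))


def test_averaging_merges_close_points():
    cohort = make_cohort([("A", "weight", 100, 10.0), ("A", "weight", 110, 12.0)])
    out = average_close_measurements(cohort)
    assert out.n_points() == 1
    assert out.points.loc[0, "age_days"] == pytest.approx(105.0)
    assert out.points.loc[0, "value"] == pytest.approx(11.0)


def test_averaging_leaves_separated_points():
    cohort = make_cohort([("A", "weight", 100, 10.0), ("A", "weight", 120, 12.0)])
    assert average_close_measurements(cohort).n_points() == 2


def test_averaging_chain_merges_transitively():
    cohort = make_cohort([("A", "weight", 100, 9.0), ("A", "weight", 110, 10.0),
                          ("A", "weight", 120, 11.0)])
    out = average_close_measurements(cohort)
    assert out.n_points() == 1
    assert out.points.loc[0, "value"] == pytest.approx(10.0)


def test_averaging_idempotent_and_never_grows(small_cohort):
    cohort, _ = small_cohort
    once = average_close_measurements(cohort)
    twice = average_close_measurements(once)
    assert once.n_points() <= cohort.n_points()
    assert np.allclose(
        once.sorted_points()[["age_days", "value"]].to_numpy(float),
        twice.sorted_points()[["age_days", "value"]].to_numpy(float))
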
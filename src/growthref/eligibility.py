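"""Point-eligibility rules for each growth curve.

Which cleaned measurements may enter a given curve depends on
prematurity (premature subjects contribute nothing before age 2),
gestational-age knowledge (unknown GA is treated like prematurity
unless a birth measurement clears an achondroplasia birth reference at
-2 SD), growth-modulating treatment (points at or after the first
limb-lengthening / growth-hormone / trial event are censored), and —
for head circumference only — neurosurgical history (optional).

Every input point of the curve's sex and measure lands in exactly one
of {included, excluded}; exclusions carry the first matching reason in
the fixed rule order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .records import (
    Cohort, ReferenceTable, TREATMENT_KINDS, age_days_to_months,
)

PREMATURE_GA_WEEKS = 37.0          # term is >= 37.0 weeks
UNDER_TWO_DAYS = 24.0 * 30.4375    # "up to 2 years": age < 24.0 months
BIRTH_WINDOW_DAYS = 3.0

EXCLUSION_REASONS = (
    "premature_under_2y", "unknown_ga_under_2y", "post_treatment",
    "post_neuro", "out_of_domain",
)


@dataclass(frozen=True)
class CurveSpec:
    """What curve is being built: sex, measure, index kind and domain."""

    sex: str
    measure: str
    index_kind: str = "age_months"            # or "height_cm"
    age_domain: tuple[float, float] = (0.0, 216.0)  # months, or cm for height_cm
    include_post_neuro: bool = True           # head circumference only

    def __post_init__(self):
        lo, hi = self.age_domain
        if not lo < hi:
            raise ConfigurationError(f"degenerate domain {self.age_domain}")


@dataclass
class EligiblePoints:
    """Partition of the candidate points with a per-exclusion reason ledger."""

    points: pd.DataFrame
    ledger: pd.DataFrame  # columns: subject_id, measure, age_days, value, reason
    spec: CurveSpec = None

    def n_included(self) -> int:
        return len(self.points)

    def n_excluded(self) -> int:
        return len(self.ledger)


def _birth_ok(sub_points: pd.DataFrame, birth_reference: ReferenceTable,
              birth_window_days: float) -> bool:
    """Unknown-GA fallback: does a birth measurement clear -2 SD?"""
    from .zscores import zscore  # local import; zscores depends on records only

    births = sub_points[sub_points["age_days"] <= birth_window_days]
    births = births[births["measure"] == birth_reference.measure]
    if len(births) == 0:
        return False
    for _, row in births.iterrows():
        idx = age_days_to_months(row["age_days"])
        g = birth_reference.grid
        idx = float(np.clip(idx, g[0], g[-1]))
        if zscore(row["value"], idx, birth_reference).z >= -2.0:
            return True
    return False


def select_for_curve(
    cohort: Cohort,
    spec: CurveSpec,
    birth_reference: ReferenceTable | None = None,
    unknown_ga_fallback: bool = False,
    birth_window_days: float = BIRTH_WINDOW_DAYS,
) -> EligiblePoints:
    """Partition the cohort's points of ``spec.sex`` / ``spec.measure``.

    Rules, in order (first match wins in the ledger):

    1. prematurity — GA < 37 weeks: exclude points at age < 24 months;
    2. unknown GA — exclude points at age < 24 months, unless the
       fallback is enabled and a birth value clears -2 SD on the
       supplied birth reference;
    3. treatment censoring — exclude points at or after the earliest
       treatment event;
    4. neurosurgery — head circumference only, when
       ``spec.include_post_neuro`` is false: exclude points at or after
       the earliest neuro event;
    5. domain clipping.
    """
    if unknown_ga_fallback and birth_reference is None:
        raise ConfigurationError(
            "unknown-GA birth fallback requested but no birth reference table supplied"
        )

    merged = cohort.merged_points()
    cand = merged[(merged["sex"] == spec.sex) & (merged["measure"] == spec.measure)]
    cand = cand.sort_values(["subject_id", "age_days"], kind="mergesort").reset_index(drop=True)

    ga = cand["gestational_age_weeks"].to_numpy(float)
    age = cand["age_days"].to_numpy(float)
    reason = np.full(len(cand), "", dtype=object)

    premature = np.isfinite(ga) & (ga < PREMATURE_GA_WEEKS)
    reason[(reason == "") & premature & (age < UNDER_TWO_DAYS)] = "premature_under_2y"

    unknown = ~np.isfinite(ga)
    if unknown.any():
        cleared_ids: set = set()
        if unknown_ga_fallback:
            all_pts = cohort.points
            for sid in cand.loc[unknown, "subject_id"].unique():
                if _birth_ok(all_pts[all_pts["subject_id"] == sid],
                             birth_reference, birth_window_days):
                    cleared_ids.add(sid)
        not_cleared = unknown & ~cand["subject_id"].isin(cleared_ids).to_numpy()
        reason[(reason == "") & not_cleared & (age < UNDER_TWO_DAYS)] = "unknown_ga_under_2y"

    ev = cohort.events
    treat = ev[ev["event_kind"].isin(TREATMENT_KINDS)]
    if len(treat):
        first_treat = treat.groupby("subject_id")["age_days"].min()
        cutoff = cand["subject_id"].map(first_treat).to_numpy(float)
        post = np.isfinite(cutoff) & (age >= cutoff)
        reason[(reason == "") & post] = "post_treatment"

    if spec.measure == "head_circumference" and not spec.include_post_neuro:
        neuro = ev[~ev["event_kind"].isin(TREATMENT_KINDS)]
        if len(neuro):
            first_neuro = neuro.groupby("subject_id")["age_days"].min()
            cutoff = cand["subject_id"].map(first_neuro).to_numpy(float)
            post = np.isfinite(cutoff) & (age >= cutoff)
            reason[(reason == "") & post] = "post_neuro"

    if spec.index_kind == "age_months":
        idx = age_days_to_months(age)
        lo, hi = spec.age_domain
        out = (idx < lo) | (idx > hi)
        reason[(reason == "") & out] = "out_of_domain"
    # height_cm curves clip on height at pairing time (reference_builder)

    keep = reason == ""
    cols = ["subject_id", "measure", "age_days", "value", "position"]
    ledger = cand.loc[~keep, cols].copy()
    ledger["reason"] = reason[~keep]
    return EligiblePoints(
        points=cand.loc[keep].reset_index(drop=True),
        ledger=ledger.reset_index(drop=True),
        spec=spec,
    )


def sensitivity_compare(cohort: Cohort, spec: CurveSpec, config=None):
    """Head-circumference neurosurgery sensitivity analysis.

    Builds the curve set twice — keeping vs omitting post-neurosurgery
    points — and reports the maximum absolute difference over the grid
    per percentile level.
    """
    from .reference_builder import BuilderConfig, build_curve

    if spec.measure != "head_circumference":
        raise ConfigurationError("sensitivity_compare applies to head circumference only")
    config = config or BuilderConfig()
    with_spec = CurveSpec(spec.sex, spec.measure, spec.index_kind,
                          spec.age_domain, include_post_neuro=True)
    without_spec = CurveSpec(spec.sex, spec.measure, spec.index_kind,
                             spec.age_domain, include_post_neuro=False)
    res_with = build_curve(cohort, with_spec, config)
    res_without = build_curve(cohort, without_spec, config)
    t_with, t_without = res_with["table"], res_without["table"]
    diffs = {}
    for col in ReferenceTable.PCT_COLS:
        diffs[col] = float(np.max(np.abs(
            t_with.data[col].to_numpy(float) - t_without.data[col].to_numpy(float)
        )))
    return t_with, t_without, diffs
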
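"""Data-cleaning screens for longitudinal anthropometry.

Six deterministic rules flag values needing review; flags never modify
the data.  Resolution (keep / drop / replace) is a separate, audited
step, and near-duplicate measurements taken < 15 days apart are
collapsed to their arithmetic mean.

Rules
-----
stature_jump  |Δ stature| > 5 cm between consecutive values (any gap)
stature_max   stature > 139.9 cm
weight_max    weight > 69 kg
weight_jump   |Δ weight| > 5 kg between values < 182 days apart
hc_max        head circumference > 60 cm
hc_jump       |Δ HC| > 3 cm between consecutive values < 182 days apart

"Consecutive" means adjacent after sorting by age within each
subject x measure series.  Jump rules use absolute differences:
growth should be monotone, so large drops are as suspect as large
gains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvariantError
from .records import Cohort

RULE_IDS = (
    "stature_jump", "stature_max", "weight_max",
    "weight_jump", "hc_max", "hc_jump",
)

STATURE_MAX_CM = 139.9
WEIGHT_MAX_KG = 69.0
HC_MAX_CM = 60.0
STATURE_JUMP_CM = 5.0
WEIGHT_JUMP_KG = 5.0
HC_JUMP_CM = 3.0
SIX_MONTHS_DAYS = 182.0


@dataclass(frozen=True)
class CleaningFlag:
    subject_id: str
    measure: str
    rule_id: str
    age_days: float
    prev_age_days: float | None
    detail: str

    def __post_init__(self):
        if self.rule_id not in RULE_IDS:
            raise InvariantError(f"unknown cleaning rule {self.rule_id!r}")


def flags_to_frame(flags: list[CleaningFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": f.subject_id, "measure": f.measure,
                "rule_id": f.rule_id, "age_days": f.age_days,
                "prev_age_days": f.prev_age_days, "detail": f.detail,
            }
            for f in flags
        ],
        columns=["subject_id", "measure", "rule_id", "age_days", "prev_age_days", "detail"],
    )


# ----------------------------------------------------------------------

def _series_flags(sid: str, measure: str, ages: np.ndarray, vals: np.ndarray):
    """Flags for one sorted subject x measure series."""
    out: list[CleaningFlag] = []
    if measure == "stature":
        for a, v in zip(ages[vals > STATURE_MAX_CM], vals[vals > STATURE_MAX_CM]):
            out.append(CleaningFlag(sid, measure, "stature_max", a, None,
                                    f"stature {v:g} cm > {STATURE_MAX_CM} cm"))
        d = np.abs(np.diff(vals))
        for i in np.flatnonzero(d > STATURE_JUMP_CM):
            out.append(CleaningFlag(
                sid, measure, "stature_jump", ages[i + 1], ages[i],
                f"stature change {vals[i]:g} -> {vals[i + 1]:g} cm "
                f"(|Δ| {d[i]:g} > {STATURE_JUMP_CM} cm)"))
    elif measure == "weight":
        for a, v in zip(ages[vals > WEIGHT_MAX_KG], vals[vals > WEIGHT_MAX_KG]):
            out.append(CleaningFlag(sid, measure, "weight_max", a, None,
                                    f"weight {v:g} kg > {WEIGHT_MAX_KG} kg"))
        # any pair (not only adjacent) closer than 6 months, per the rule's
        # wording "between 2 values obtained in < 6 months"
        for i in range(len(ages)):
            for j in range(i + 1, len(ages)):
                gap = ages[j] - ages[i]
                if gap >= SIX_MONTHS_DAYS:
                    break
                dv = abs(vals[j] - vals[i])
                if dv > WEIGHT_JUMP_KG:
                    out.append(CleaningFlag(
                        sid, measure, "weight_jump", ages[j], ages[i],
                        f"weight change {vals[i]:g} -> {vals[j]:g} kg over "
                        f"{gap:g} days (|Δ| {dv:g} > {WEIGHT_JUMP_KG} kg)"))
    elif measure == "head_circumference":
        for a, v in zip(ages[vals > HC_MAX_CM], vals[vals > HC_MAX_CM]):
            out.append(CleaningFlag(sid, measure, "hc_max", a, None,
                                    f"head circumference {v:g} cm > {HC_MAX_CM} cm"))
        d = np.abs(np.diff(vals))
        gaps = np.diff(ages)
        for i in np.flatnonzero((d > HC_JUMP_CM) & (gaps < SIX_MONTHS_DAYS)):
            out.append(CleaningFlag(
                sid, measure, "hc_jump", ages[i + 1], ages[i],
                f"HC change {vals[i]:g} -> {vals[i + 1]:g} cm over "
                f"{gaps[i]:g} days (|Δ| {d[i]:g} > {HC_JUMP_CM} cm)"))
    return out


def flag_errors(cohort: Cohort) -> list[CleaningFlag]:
    """Pure report of all rule violations; the cohort is not modified."""
    flags: list[CleaningFlag] = []
    pts = cohort.sorted_points()
    for (sid, measure), grp in pts.groupby(["subject_id", "measure"], sort=True):
        flags.extend(_series_flags(
            sid, measure,
            grp["age_days"].to_numpy(float), grp["value"].to_numpy(float),
        ))
    return flags


# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Resolution:
    """Disposition of one flag: action in {keep, drop, replace}."""

    action: str = "drop"
    value: float | None = None


_HARD_BOUNDS = {
    "stature": STATURE_MAX_CM,
    "weight": WEIGHT_MAX_KG,
    "head_circumference": HC_MAX_CM,
}


def resolve_flags(
    cohort: Cohort,
    flags: list[CleaningFlag],
    resolutions: dict[int, Resolution] | None = None,
    iterate_jumps: bool = True,
) -> tuple[Cohort, pd.DataFrame]:
    """Apply per-flag dispositions; default is to drop every flagged point.

    Because dropping a point creates new adjacencies, jump rules are
    re-evaluated after applying drops, iterating (drop-only) to a fixed
    point; the hard-bound rules cannot re-fire.  Returns the new cohort
    and an audit frame of every change.

    Replacement values violating a hard bound are refused.
    """
    resolutions = resolutions or {}
    audit: list[dict] = []
    work = cohort.copy()

    def apply_once(flgs):
        nonlocal work
        pts = work.points
        to_drop: list[int] = []
        for i, f in enumerate(flgs):
            res = resolutions.get(i, Resolution("drop"))
            if res.action == "keep":
                continue
            key = (pts["subject_id"] == f.subject_id) & (pts["measure"] == f.measure) \
                & (np.isclose(pts["age_days"], f.age_days))
            idx = [j for j in pts.index[key] if j not in to_drop]
            if not idx:
                continue
            if res.action == "replace":
                if res.value is None or res.value > _HARD_BOUNDS[f.measure] or res.value <= 0:
                    raise InvariantError(
                        f"replacement {res.value!r} violates hard bound for {f.measure}"
                    )
                old = pts.loc[idx[0], "value"]
                pts.loc[idx[0], "value"] = res.value
                audit.append({"subject_id": f.subject_id, "measure": f.measure,
                              "age_days": f.age_days, "action": "replace",
                              "old_value": old, "new_value": res.value,
                              "rule_id": f.rule_id})
            elif res.action == "drop":
                audit.append({"subject_id": f.subject_id, "measure": f.measure,
                              "age_days": f.age_days, "action": "drop",
                              "old_value": pts.loc[idx[0], "value"],
                              "new_value": np.nan, "rule_id": f.rule_id})
                to_drop.append(idx[0])
            else:
                raise InvariantError(f"unknown resolution action {res.action!r}")
        if to_drop:
            work.points = pts.drop(index=to_drop).reset_index(drop=True)
        return bool(to_drop)

    apply_once(flags)
    if iterate_jumps:
        # explicit resolutions applied above are one-shot; later rounds drop
        for _ in range(100):
            new_flags = flag_errors(work)
            resolutions = {}
            if not new_flags or not apply_once(new_flags):
                break

    audit_frame = pd.DataFrame(
        audit, columns=["subject_id", "measure", "age_days", "action",
                        "old_value", "new_value", "rule_id"])
    return work, audit_frame


# ----------------------------------------------------------------------

def average_close_measurements(cohort: Cohort, window_days: float = 15.0) -> Cohort:
    """Collapse runs of measurements taken < ``window_days`` apart.

    Within each subject x measure series, maximal chains whose
    consecutive gaps are all strictly below the window are replaced by a
    single point at the mean age with the mean value (chain-merging:
    the transitive closure of the close-pair relation).  Idempotent in
    practice because clinic revisit gaps greatly exceed the window; a
    second pass only re-merges if averaging itself created new
    sub-window gaps.
    """
    pts = cohort.sorted_points()
    out_rows = []
    for (sid, measure), grp in pts.groupby(["subject_id", "measure"], sort=False):
        ages = grp["age_days"].to_numpy(float)
        vals = grp["value"].to_numpy(float)
        pos = grp["position"].to_numpy(object)
        if len(ages) == 0:
            continue
        run_id = np.concatenate([[0], np.cumsum(np.diff(ages) >= window_days)])
        for r in np.unique(run_id):
            m = run_id == r
            out_rows.append({
                "subject_id": sid, "measure": measure,
                "age_days": float(ages[m].mean()),
                "value": float(vals[m].mean()),
                "position": pos[m][0],
            })
    new_points = pd.DataFrame(
        out_rows, columns=["subject_id", "measure", "age_days", "value", "position"])
    return Cohort(cohort.subjects.copy(), new_points, cohort.events.copy())


# ----------------------------------------------------------------------

def studentized_outlier_screen(
    cohort: Cohort, threshold: float = 4.0, min_points: int = 5
) -> pd.DataFrame:
    """Optional extra screen (disabled by default in the pipeline).

    Flags points whose studentized residual from a per-subject linear
    fit of value on age exceeds ``threshold``; needs >= ``min_points``
    in the series.
    """
    rows = []
    for (sid, measure), grp in cohort.sorted_points().groupby(["subject_id", "measure"]):
        if len(grp) < min_points:
            continue
        x = grp["age_days"].to_numpy(float)
        y = grp["value"].to_numpy(float)
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(y) - 2
        s = np.sqrt((resid**2).sum() / dof) if dof > 0 else 0.0
        if s <= 0:
            continue
        h = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X)
        t = resid / (s * np.sqrt(np.maximum(1.0 - h, 1e-9)))
        for a, v, ti in zip(x[np.abs(t) > threshold], y[np.abs(t) > threshold],
                            t[np.abs(t) > threshold]):
            rows.append({"subject_id": sid, "measure": measure, "age_days": a,
                         "value": v, "studentized_residual": ti})
    return pd.DataFrame(
        rows, columns=["subject_id", "measure", "age_days", "value",
                       "studentized_residual"])
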
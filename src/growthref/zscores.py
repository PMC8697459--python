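"""Z-scores with asymmetric SDs, extreme-weight exclusion and summaries.

A measurement's Z-score is computed against a reference table's mean
with side-specific SDs: values above the interpolated mean use the
upper SD, values at or below it use the lower SD (the lower-SD subset
is defined by "less than or equal to" the mean).  This keeps +2 and -2
thresholds meaningful for right-skewed weight without transforming the
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, RangeError
from .records import ReferenceTable, age_days_to_months

AGE_GROUP_LABELS = ("birth", "0-5y", "5-10y", "10-15y", "15-20y", ">20y")
_YEAR_DAYS = 365.25


@dataclass(frozen=True)
class ZScore:
    subject_id: str | None
    measure: str
    index: float
    value: float
    z: float
    side: str  # "upper" | "lower"


def _table_arrays(table):
    """(grid, mean, sd_upper, sd_lower) from a ReferenceTable or SdCurvePair."""
    if isinstance(table, ReferenceTable):
        d = table.data
        return (d["index"].to_numpy(float), d["mean"].to_numpy(float),
                d["sd_upper"].to_numpy(float), d["sd_lower"].to_numpy(float))
    return None


def _interp_msd(index, table):
    arrays = _table_arrays(table)
    index = np.asarray(index, dtype=float)
    if arrays is not None:
        grid, mean, sd_u, sd_l = arrays
        if np.any(index < grid[0]) or np.any(index > grid[-1]):
            bad = index[(index < grid[0]) | (index > grid[-1])]
            raise RangeError(
                f"index {np.atleast_1d(bad)[0]:g} outside table grid "
                f"[{grid[0]:g}, {grid[-1]:g}] (no extrapolation)")
        return (np.interp(index, grid, mean), np.interp(index, grid, sd_u),
                np.interp(index, grid, sd_l))
    # SdCurvePair (duck-typed): curves evaluable over their domain
    lo, hi = table.domain
    if np.any(index < lo) or np.any(index > hi):
        raise RangeError(f"index outside SD-curve domain [{lo:g}, {hi:g}]")
    return (np.asarray(table.mean_curve(index), float),
            np.asarray(table.sd_upper_curve(index), float),
            np.asarray(table.sd_lower_curve(index), float))


def zscore(value: float, index: float, table, subject_id=None,
           measure: str | None = None) -> ZScore:
    """Z-score of one value at one index against a reference table.

    Mean and SDs are linearly interpolated between grid rows;
    ``z = (value - mean) / sd_upper`` above the mean, else
    ``/ sd_lower`` (ties use the lower side).
    """
    mean, sd_u, sd_l = _interp_msd(float(index), table)
    dev = float(value) - float(mean)
    side = "upper" if dev > 0 else "lower"
    z = dev / float(sd_u if dev > 0 else sd_l)
    meas = measure or (table.measure if isinstance(table, ReferenceTable) else "weight")
    return ZScore(subject_id, meas, float(index), float(value), float(z), side)


def zscore_frame(points: pd.DataFrame, table, spec=None) -> pd.DataFrame:
    """Vectorised z-scoring of a points frame (adds ``z`` and ``side``)."""
    if "height_cm" in points.columns and (
            spec is not None and spec.index_kind == "height_cm"):
        idx = points["height_cm"].to_numpy(float)
    else:
        idx = age_days_to_months(points["age_days"].to_numpy(float))
    mean, sd_u, sd_l = _interp_msd(idx, table)
    dev = points["value"].to_numpy(float) - mean
    z = np.where(dev > 0, dev / sd_u, dev / sd_l)
    out = points.copy()
    out["z"] = z
    out["side"] = np.where(dev > 0, "upper", "lower")
    return out


def invert_zscore(z: float, index: float, table) -> float:
    """Value whose z-score at ``index`` equals ``z`` (exact inverse)."""
    mean, sd_u, sd_l = _interp_msd(float(index), table)
    return float(mean + z * (sd_u if z > 0 else sd_l))


# ----------------------------------------------------------------------

def exclude_extreme_weights(points: pd.DataFrame, table, threshold: float = 3.0,
                            spec=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass partition of weight points at ``|z| > threshold``.

    The reference is built from the pre-exclusion points; no refitting
    happens between exclusion and curve construction.  The excluded
    frame carries the z values.
    """
    scored = zscore_frame(points, table, spec)
    mask = np.abs(scored["z"].to_numpy(float)) > threshold
    kept = points.loc[~mask].reset_index(drop=True)
    excluded = scored.loc[mask].reset_index(drop=True)
    return kept, excluded


# ----------------------------------------------------------------------

def age_group(age_days) -> np.ndarray:
    """Bin ages into birth / 0-5 / 5-10 / 10-15 / 15-20 / >20 years."""
    a = np.asarray(age_days, dtype=float)
    out = np.full(a.shape, ">20y", dtype=object)
    out[a <= 20 * _YEAR_DAYS] = "15-20y"
    out[a <= 15 * _YEAR_DAYS] = "10-15y"
    out[a <= 10 * _YEAR_DAYS] = "5-10y"
    out[a <= 5 * _YEAR_DAYS] = "0-5y"
    out[a <= 3.0] = "birth"
    return out


def secular_summary(zscores: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Five-number z summaries by birth decade, age group and sex.

    ``zscores`` needs columns subject_id, age_days, z; subjects supply
    sex and birth_decade.  Points from subjects with unknown decade are
    summarised under decade ``"unknown"``.  The cells partition the
    z-scored points.
    """
    df = zscores.merge(subjects[["subject_id", "sex", "birth_decade"]],
                       on="subject_id", how="left")
    df["birth_decade"] = df["birth_decade"].fillna("unknown")
    df["age_group"] = age_group(df["age_days"].to_numpy(float))
    rows = []
    for (dec, grp, sex), cell in df.groupby(["birth_decade", "age_group", "sex"],
                                            sort=True):
        z = cell["z"].to_numpy(float)
        rows.append({
            "birth_decade": dec, "age_group": grp, "sex": sex, "n": len(z),
            "min": z.min(), "q1": np.quantile(z, 0.25),
            "median": np.quantile(z, 0.5), "q3": np.quantile(z, 0.75),
            "max": z.max(), "n_outliers": int((np.abs(z) > 3).sum()),
        })
    return pd.DataFrame(rows, columns=["birth_decade", "age_group", "sex", "n",
                                       "min", "q1", "median", "q3", "max",
                                       "n_outliers"])


# ----------------------------------------------------------------------

DAYS_PER_MONTH = 30.4375


def weight_gain_per_day(mean_curve, intervals=((0, 1), (1, 3), (3, 6), (6, 12))
                        ) -> dict:
    """Average weight gain in g/day over monthly intervals of a mean curve."""
    out = {}
    for a, b in intervals:
        da, db = a * DAYS_PER_MONTH, b * DAYS_PER_MONTH
        gain_kg = float(mean_curve(float(b)) - mean_curve(float(a)))
        out[(a, b)] = 1000.0 * gain_kg / (db - da)
    return out


def birth_summary(points: pd.DataFrame, birth_window_days: float = 3.0,
                  comparator_mean: float | None = None) -> dict:
    """Mean, SD and normal-theory 95% CI of birth measurements.

    ``points`` should already be restricted to one sex x measure; the
    birth window is age <= ``birth_window_days``.  An optional
    comparator mean (e.g. a WHO birth mean) is tested against the CI.
    """
    births = points[points["age_days"] <= birth_window_days]["value"].to_numpy(float)
    if births.size < 2:
        raise InsufficientDataError(
            f"birth summary needs >= 2 points, got {births.size}")
    mean = float(births.mean())
    sd = float(births.std(ddof=1))
    half = 1.96 * sd / np.sqrt(births.size)
    out = {"n": int(births.size), "mean": mean, "sd": sd,
           "ci_low": mean - half, "ci_high": mean + half}
    if comparator_mean is not None:
        out["comparator_mean"] = float(comparator_mean)
        out["comparator_outside_ci"] = bool(
            comparator_mean < out["ci_low"] or comparator_mean > out["ci_high"])
    return out


def adult_height_summary(points: pd.DataFrame, subjects: pd.DataFrame,
                         adult_age_months: float = 216.0) -> pd.DataFrame:
    """Per-sex mean, SD and n of each subject's last adult stature."""
    cutoff_days = adult_age_months * DAYS_PER_MONTH
    stat = points[(points["measure"] == "stature")
                  & (points["age_days"] >= cutoff_days)]
    if len(stat) == 0:
        return pd.DataFrame(columns=["sex", "n", "mean", "sd"])
    last = stat.sort_values("age_days").groupby("subject_id").tail(1)
    last = last.merge(subjects[["subject_id", "sex"]], on="subject_id", how="left")
    rows = []
    for sex, grp in last.groupby("sex", sort=True):
        v = grp["value"].to_numpy(float)
        rows.append({"sex": sex, "n": len(v), "mean": float(v.mean()),
                     "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan")})
    return pd.DataFrame(rows, columns=["sex", "n", "mean", "sd"])
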
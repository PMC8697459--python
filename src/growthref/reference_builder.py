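"""Construction of smoothed percentile, mean and SD curves.

The multi-step recipe: age-windowed empirical percentiles on an integer
monthly (or per-centimeter) grid, penalized cubic-spline smoothing of
each percentile series (weight stratified at 3 years with a seam
blend), knot-reduction / isotonic enforcement of age-monotonicity and
cross-level non-crossing, a quadratic second-round refit over the
sparse tail of the domain, plus spline mean curves and windowed
upper/lower (asymmetric) SD curves for Z-scoring right-skewed weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError, FitError, InvariantError
from .pspline import PenalizedCubicSpline
from .records import (
    PERCENTILE_LEVELS, ReferenceTable, age_days_to_months,
)
from .eligibility import CurveSpec, EligiblePoints, select_for_curve

__all__ = [
    "BuilderConfig", "EmpiricalPercentileSet", "SmoothedCurveSet", "SdCurvePair",
    "window_halfwidth", "empirical_percentiles", "smooth_percentiles",
    "smooth_weight_stratified", "enforce_monotone", "polynomial_refit",
    "estimate_mean_curve", "estimate_asymmetric_sd", "pair_weight_height",
    "build_weight_for_height", "build_reference_table", "build_curve",
]

_LADDER_EPS = 1e-4  # strictness margin between adjacent percentile levels


@dataclass(frozen=True)
class BuilderConfig:
    """Hyperparameters of the curve-construction machinery.

    Knot counts and the GCV override are the P-spline controls; windows
    are in index units (months on age grids, cm on height grids).
    """

    levels: tuple = PERCENTILE_LEVELS
    min_window_n: int = 10
    n_knots: int = 20               # single-segment fits over 0-216 months
    n_knots_young: int = 8          # weight segment 0-36 months
    n_knots_old: int = 10           # weight segment 36-216 months; other subranges
    n_knots_height: int = 10        # weight-for-height fits
    knot_floor: int = 4
    lam: float | None = None        # None = GCV
    seam: tuple = (34.0, 38.0)      # weight stratification cross-fade, months
    sd_window: float = 2.0          # half-width for empirical SD windows
    sd_center: str = "mean_curve"   # or "subset_mean"
    sd_rel_floor: float = 1e-3
    quantile_method: str = "linear"  # numpy's type-7 convention
    height_domains: dict = field(default_factory=lambda: {
        "male": (50.0, 140.0), "female": (50.0, 134.0)})
    refit_domains: dict = field(default_factory=lambda: {
        "stature": (156.0, 216.0), "weight": (156.0, 216.0),
        "head_circumference": (48.0, 60.0)})
    exclusion_threshold: float = 3.0


# ----------------------------------------------------------------------
# windows and empirical percentiles
# ----------------------------------------------------------------------

def window_halfwidth(age_months: float) -> float:
    """Age-dependent percentile window half-width, in months.

    +/- 0.5 months through the first year, +/- 1 month over >1-3 years,
    +/- 3 months over >3-18 years; narrower windows are possible at
    young ages because the data are densest there.
    """
    a = np.asarray(age_months, dtype=float)
    if np.any(a < 0):
        raise ValueError("negative age")
    out = np.where(a <= 12.0, 0.5, np.where(a <= 36.0, 1.0, 3.0))
    return float(out) if np.isscalar(age_months) else out


@dataclass
class EmpiricalPercentileSet:
    """Raw windowed percentile estimates on an integer grid.

    ``values``: DataFrame indexed by grid with one column per level
    (NaN where the window held fewer than ``min_window_n`` points);
    ``n_window``: points per window.
    """

    index_kind: str
    grid: np.ndarray
    levels: tuple
    values: pd.DataFrame
    n_window: np.ndarray

    def level_series(self, level) -> tuple[np.ndarray, np.ndarray]:
        v = self.values[level].to_numpy(float)
        ok = np.isfinite(v)
        return self.grid[ok].astype(float), v[ok]


def _index_values(points: pd.DataFrame, spec: CurveSpec) -> np.ndarray:
    if spec.index_kind == "age_months":
        return age_days_to_months(points["age_days"].to_numpy(float))
    if "height_cm" not in points.columns:
        raise ConfigurationError("height-indexed percentile input needs a height_cm column")
    return points["height_cm"].to_numpy(float)


def empirical_percentiles(
    points: EligiblePoints | pd.DataFrame,
    spec: CurveSpec,
    config: BuilderConfig = BuilderConfig(),
    levels: tuple | None = None,
) -> EmpiricalPercentileSet:
    """Windowed quantiles at each integer grid index.

    The window at grid point ``g`` collects values with
    ``|index - g| <= halfwidth`` (age-dependent half-width on age grids,
    1 cm on height grids, truncated at the domain edges); windows with
    fewer than ``min_window_n`` points yield missing values.
    """
    df = points.points if isinstance(points, EligiblePoints) else points
    levels = tuple(levels or config.levels)
    lo, hi = spec.age_domain
    grid = np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)
    vals = np.full((len(grid), len(levels)), np.nan)
    counts = np.zeros(len(grid), dtype=int)

    if len(df) == 0:
        warnings.warn("empirical_percentiles: no points in domain")
    else:
        idx = _index_values(df, spec)
        order = np.argsort(idx, kind="mergesort")
        idx_s = idx[order]
        val_s = df["value"].to_numpy(float)[order]
        for i, g in enumerate(grid):
            hw = 1.0 if spec.index_kind == "height_cm" else window_halfwidth(float(g))
            a = np.searchsorted(idx_s, g - hw, side="left")
            b = np.searchsorted(idx_s, g + hw, side="right")
            counts[i] = b - a
            if counts[i] >= config.min_window_n:
                vals[i] = np.quantile(
                    val_s[a:b], np.asarray(levels) / 100.0,
                    method=config.quantile_method,
                )
    frame = pd.DataFrame(vals, index=grid, columns=list(levels))
    return EmpiricalPercentileSet(spec.index_kind, grid, levels, frame, counts)


# ----------------------------------------------------------------------
# curve objects
# ----------------------------------------------------------------------

class BlendedCurve:
    """Linear cross-fade between two curves over [lo, hi]."""

    def __init__(self, left, right, lo: float, hi: float):
        self.left, self.right, self.lo, self.hi = left, right, lo, hi

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        w = np.clip((x - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        return (1.0 - w) * self.left(x) + w * self.right(x)


class QuadRefitCurve:
    """Base curve replaced by a quadratic on a tail domain, with fades."""

    def __init__(self, base, coef, lo, hi, domain_hi, fade: float = 1.0):
        self.base, self.coef, self.lo, self.hi = base, coef, lo, hi
        self.domain_hi = domain_hi
        self.fade = fade

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        q = np.polyval(self.coef, x)
        w = np.clip((x - (self.lo - self.fade)) / self.fade, 0.0, 1.0)
        if self.hi < self.domain_hi - 1e-9:
            w = w * np.clip(((self.hi + self.fade) - x) / self.fade, 0.0, 1.0)
        return (1.0 - w) * self.base(x) + w * q


class GridCurve:
    """Monotone (PCHIP) interpolant of grid values; projection fallback."""

    def __init__(self, grid, values):
        self._f = PchipInterpolator(np.asarray(grid, float), np.asarray(values, float),
                                    extrapolate=False)
        self.lo, self.hi = float(grid[0]), float(grid[-1])

    def __call__(self, x):
        return self._f(np.clip(np.asarray(x, dtype=float), self.lo, self.hi))


@dataclass
class SmoothedCurveSet:
    """Per-level smoothed percentile curves, evaluable over the domain."""

    index_kind: str
    domain: tuple
    levels: tuple
    curves: dict
    emp: EmpiricalPercentileSet
    config: BuilderConfig
    stratified: bool = False
    knots: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def grid(self) -> np.ndarray:
        lo, hi = self.domain
        return np.arange(int(np.ceil(lo)), int(np.floor(hi)) + 1)

    def evaluate(self, x=None) -> pd.DataFrame:
        x = self.grid if x is None else np.asarray(x, dtype=float)
        return pd.DataFrame({lv: self.curves[lv](x) for lv in self.levels}, index=x)


# ----------------------------------------------------------------------
# smoothing fits
# ----------------------------------------------------------------------

def _fit_single(x, y, domain, n_knots, config) -> PenalizedCubicSpline:
    return PenalizedCubicSpline(n_knots=n_knots, lam=config.lam).fit(x, y, domain=domain)


def _fit_level(emp: EmpiricalPercentileSet, level, domain, config,
               stratified: bool, knots):
    """(Re)fit one level's curve; ``knots`` is int, or (left, right)."""
    x, y = emp.level_series(level)
    if x.size < 4:
        raise FitError(f"level {level}: only {x.size} non-missing grid points")
    if not stratified:
        return _fit_single(x, y, domain, knots, config)
    lo, hi = domain
    s_lo, s_hi = config.seam
    split = 0.5 * (s_lo + s_hi)
    kl, kr = knots
    left_m = x <= s_hi + 1.0
    right_m = x >= s_lo - 1.0
    if left_m.sum() < 4 or right_m.sum() < 4:
        return _fit_single(x, y, domain, max(kl, kr), config)
    left = _fit_single(x[left_m], y[left_m], (lo, min(s_hi + 1.0, hi)), kl, config)
    right = _fit_single(x[right_m], y[right_m], (max(s_lo - 1.0, lo), hi), kr, config)
    return BlendedCurve(left, right, s_lo, s_hi)


def smooth_percentiles(
    emp: EmpiricalPercentileSet,
    config: BuilderConfig = BuilderConfig(),
    domain: tuple | None = None,
    n_knots: int | None = None,
) -> SmoothedCurveSet:
    """Penalized cubic-spline fit of each empirical percentile series.

    Missing grid points are bridged by the fit; the smoothing parameter
    is chosen by GCV unless fixed in the config.
    """
    if domain is None:
        domain = (float(emp.grid[0]), float(emp.grid[-1]))
    n_knots = n_knots if n_knots is not None else (
        config.n_knots if emp.index_kind == "age_months" else config.n_knots_height)
    curves, knots, diags = {}, {}, {}
    for lv in emp.levels:
        fit = _fit_level(emp, lv, domain, config, False, n_knots)
        curves[lv] = fit
        knots[lv] = n_knots
        diags[lv] = {"edf": fit.edf_, "lam": fit.lam_}
    return SmoothedCurveSet(emp.index_kind, domain, emp.levels, curves, emp,
                            config, False, knots, diags)


def smooth_weight_stratified(
    emp: EmpiricalPercentileSet,
    config: BuilderConfig = BuilderConfig(),
    domain: tuple | None = None,
    enforce: bool = True,
) -> SmoothedCurveSet:
    """Stratified weight smoothing: independent fits on 0-3 y and 3-18 y.

    The segments are blended by a linear cross-fade across the seam
    window so the composite is continuous; knot counts are then reduced
    stepwise (``enforce_monotone``) until the percentile estimates are
    age-monotone.
    """
    if domain is None:
        domain = (float(emp.grid[0]), float(emp.grid[-1]))
    curves, knots = {}, {}
    kn = (config.n_knots_young, config.n_knots_old)
    for lv in emp.levels:
        curves[lv] = _fit_level(emp, lv, domain, config, True, kn)
        knots[lv] = kn
    cs = SmoothedCurveSet(emp.index_kind, domain, emp.levels, curves, emp,
                          config, True, knots)
    return enforce_monotone(cs) if enforce else cs


# ----------------------------------------------------------------------
# monotonicity and non-crossing
# ----------------------------------------------------------------------

def _violates(vals: np.ndarray, tol: float = 1e-9) -> bool:
    return bool(np.any(np.diff(vals) < -tol))


def enforce_monotone(cs: SmoothedCurveSet, direction: str = "increasing") -> SmoothedCurveSet:
    """Make every level monotone in the index and the levels non-crossing.

    Per level: while the curve decreases anywhere on the integer grid,
    refit with one fewer knot, down to a floor; if still violated,
    replace the evaluated curve by its isotonic (pool-adjacent-
    violators) projection.  Then cross-level order is enforced by
    sorting level values at each grid point and re-smoothing once; any
    residual crossing falls back to a monotone interpolant of the
    sorted values.  Always returns a monotone, non-crossing set.
    """
    if direction not in ("increasing", "none"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    grid = cs.grid.astype(float)
    cfg = cs.config
    curves = dict(cs.curves)
    knots = dict(cs.knots)

    if direction == "increasing":
        for lv in cs.levels:
            original = curves[lv]
            orig_knots = knots[lv]
            vals = curves[lv](grid)
            while _violates(vals):
                kn = knots[lv]
                if cs.stratified:
                    kl, kr = kn
                    if max(kl, kr) <= cfg.knot_floor:
                        break
                    kn = (max(kl - 1, cfg.knot_floor), max(kr - 1, cfg.knot_floor))
                else:
                    if kn <= cfg.knot_floor:
                        break
                    kn = kn - 1
                knots[lv] = kn
                try:
                    curves[lv] = _fit_level(cs.emp, lv, cs.domain, cfg,
                                            cs.stratified, kn)
                except FitError:
                    break
                vals = curves[lv](grid)
            if _violates(vals):
                # no knot count achieved monotonicity: fall back to the
                # isotonic projection of the best-fitting (original) curve
                # rather than keeping an underfit floor-knot spline
                warnings.warn(
                    f"level {lv}: knot reduction failed; using isotonic projection")
                iso = IsotonicRegression(increasing=True).fit_transform(
                    grid, original(grid))
                curves[lv] = GridCurve(grid, iso)
                knots[lv] = orig_knots

    # cross-level non-crossing
    mat = np.column_stack([curves[lv](grid) for lv in cs.levels])
    if np.any(np.diff(mat, axis=1) <= 0):
        mat_sorted = np.sort(mat, axis=1)
        refit = {}
        for j, lv in enumerate(cs.levels):
            kn = knots[lv]
            nk = max(kn) if cs.stratified else kn
            try:
                refit[lv] = _fit_single(grid, mat_sorted[:, j], cs.domain, nk, cfg)
            except FitError:
                refit[lv] = GridCurve(grid, mat_sorted[:, j])
        mat2 = np.column_stack([refit[lv](grid) for lv in cs.levels])
        mono_ok = direction != "increasing" or not any(
            _violates(mat2[:, j]) for j in range(mat2.shape[1]))
        if np.any(np.diff(mat2, axis=1) <= 0) or not mono_ok:
            strict = np.sort(mat, axis=1)
            for j in range(1, strict.shape[1]):
                strict[:, j] = np.maximum(strict[:, j], strict[:, j - 1] + _LADDER_EPS)
            if direction == "increasing":
                iso = IsotonicRegression(increasing=True)
                for j in range(strict.shape[1]):
                    strict[:, j] = iso.fit_transform(grid, strict[:, j])
                for j in range(1, strict.shape[1]):
                    strict[:, j] = np.maximum(strict[:, j], strict[:, j - 1] + _LADDER_EPS)
            refit = {lv: GridCurve(grid, strict[:, j])
                     for j, lv in enumerate(cs.levels)}
        curves = refit

    return replace(cs, curves=curves, knots=knots)


def polynomial_refit(cs: SmoothedCurveSet, refit_domain: tuple) -> SmoothedCurveSet:
    """Second-round smoothing: quadratic-in-index refit over a tail domain.

    Each level's spline predictions on the integer grid inside
    ``refit_domain`` are least-squares fit by a quadratic, which
    replaces the curve there; a linear cross-fade over the one grid
    unit below (and above, if interior) the domain edge removes any
    step.
    """
    lo, hi = float(refit_domain[0]), float(refit_domain[1])
    if not (cs.domain[0] - 1e-9 <= lo < hi <= cs.domain[1] + 1e-9):
        raise ConfigurationError(f"refit domain {refit_domain} outside {cs.domain}")
    g = cs.grid.astype(float)
    sub = g[(g >= lo) & (g <= hi)]
    if len(sub) < 3:
        raise FitError(f"refit domain {refit_domain} has {len(sub)} grid points (< 3)")
    curves = {}
    for lv in cs.levels:
        y = cs.curves[lv](sub)
        coef = np.polyfit(sub, y, 2)
        curves[lv] = QuadRefitCurve(cs.curves[lv], coef, lo, hi, cs.domain[1])
    return replace(cs, curves=curves)


# ----------------------------------------------------------------------
# mean and SD curves
# ----------------------------------------------------------------------

class FlooredSdCurve:
    """SD spline floored at a small positive fraction of the mean."""

    def __init__(self, sd_curve, mean_curve, rel_floor: float):
        self.sd_curve, self.mean_curve, self.rel_floor = sd_curve, mean_curve, rel_floor

    def __call__(self, x):
        floor = np.maximum(self.rel_floor * np.abs(self.mean_curve(x)), 1e-6)
        return np.maximum(self.sd_curve(x), floor)


@dataclass
class SdCurvePair:
    """Mean curve plus upper / lower SD curves over a common domain."""

    mean_curve: object
    sd_upper_curve: object
    sd_lower_curve: object
    domain: tuple

    @property
    def symmetric(self) -> bool:
        return self.sd_upper_curve is self.sd_lower_curve


def estimate_mean_curve(
    points: EligiblePoints | pd.DataFrame,
    spec: CurveSpec,
    config: BuilderConfig = BuilderConfig(),
    domain: tuple | None = None,
):
    """Penalized cubic-spline regression of value on index over all points."""
    df = points.points if isinstance(points, EligiblePoints) else points
    if len(df) < 20:
        raise FitError(f"mean curve needs >= 20 points, got {len(df)}")
    idx = _index_values(df, spec)
    if domain is None:
        domain = spec.age_domain
    n_knots = config.n_knots if spec.index_kind == "age_months" else config.n_knots_height
    return _fit_single(idx, df["value"].to_numpy(float), domain, n_knots, config)


def estimate_asymmetric_sd(
    points: EligiblePoints | pd.DataFrame,
    mean_curve,
    spec: CurveSpec,
    config: BuilderConfig = BuilderConfig(),
    symmetric: bool = False,
    domain: tuple | None = None,
) -> SdCurvePair:
    """Windowed upper / lower SD curves about the mean curve.

    Points are split at the mean (ties to the lower side); at each
    integer index the empirical SD on each side is the RMS deviation
    from the mean curve over values within ``sd_window`` index units
    (or, with ``sd_center="subset_mean"``, the subset's own SD); the
    empirical series are smoothed by penalized cubic splines and
    floored at a small positive fraction of the mean.  With
    ``symmetric=True`` a single SD series from all residuals serves
    both sides.
    """
    df = points.points if isinstance(points, EligiblePoints) else points
    if domain is None:
        domain = spec.age_domain
    idx = _index_values(df, spec)
    val = df["value"].to_numpy(float)
    mu = mean_curve(idx)
    resid = val - mu
    upper = resid > 0

    grid = np.arange(int(np.ceil(domain[0])), int(np.floor(domain[1])) + 1)
    order = np.argsort(idx, kind="mergesort")
    idx_s, resid_s, upper_s = idx[order], resid[order], upper[order]

    def series(mask_side) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for g in grid:
            a = np.searchsorted(idx_s, g - config.sd_window, side="left")
            b = np.searchsorted(idx_s, g + config.sd_window, side="right")
            r = resid_s[a:b][mask_side[a:b]] if mask_side is not None else resid_s[a:b]
            if r.size >= config.min_window_n:
                if config.sd_center == "subset_mean":
                    sd = float(np.std(r, ddof=1))
                else:
                    sd = float(np.sqrt(np.mean(r**2)))
                xs.append(float(g))
                ys.append(sd)
        return np.asarray(xs), np.asarray(ys)

    def fit_side(mask_side):
        xs, ys = series(mask_side)
        if xs.size < 4:
            raise FitError("too few windows with enough points for an SD curve")
        sp = _fit_single(xs, ys, domain, config.n_knots, config)
        return FlooredSdCurve(sp, mean_curve, config.sd_rel_floor)

    if symmetric:
        sd = fit_side(None)
        return SdCurvePair(mean_curve, sd, sd, domain)
    return SdCurvePair(mean_curve, fit_side(upper_s), fit_side(~upper_s), domain)


# ----------------------------------------------------------------------
# weight-for-height
# ----------------------------------------------------------------------

def pair_weight_height(points: pd.DataFrame) -> pd.DataFrame:
    """Pair same-subject same-age stature and weight measurements.

    Returns columns ``subject_id, age_days, height_cm, value`` (value =
    weight in kg).  Pairing assumes the <15-day averaging has already
    collapsed near-duplicate visits.
    """
    stat = points[points["measure"] == "stature"][["subject_id", "age_days", "value"]]
    wt = points[points["measure"] == "weight"][["subject_id", "age_days", "value"]]
    paired = stat.rename(columns={"value": "height_cm"}).merge(
        wt, on=["subject_id", "age_days"], how="inner")
    return paired[["subject_id", "age_days", "height_cm", "value"]]


def build_weight_for_height(
    paired: pd.DataFrame,
    spec: CurveSpec,
    config: BuilderConfig = BuilderConfig(),
) -> tuple[SmoothedCurveSet, SdCurvePair, EmpiricalPercentileSet]:
    """Weight percentile / mean / SD curves indexed by height (cm).

    +/- 1 cm windows on the integer-centimeter grid over the
    sex-specific height domain; smoothing, monotonicity and
    non-crossing enforcement reuse the age-curve machinery.
    """
    lo, hi = spec.age_domain  # here: the height domain in cm
    sub = paired[(paired["height_cm"] >= lo) & (paired["height_cm"] <= hi)]
    if len(sub) == 0:
        raise FitError("no paired weight-height observations in the height domain")
    emp = empirical_percentiles(sub, spec, config)
    cs = smooth_percentiles(emp, config, domain=(lo, hi))
    cs = enforce_monotone(cs)
    mean_curve = estimate_mean_curve(sub, spec, config, domain=(lo, hi))
    sd_pair = estimate_asymmetric_sd(sub, mean_curve, spec, config, domain=(lo, hi))
    return cs, sd_pair, emp


# ----------------------------------------------------------------------
# reference-table assembly and the per-curve pipeline
# ----------------------------------------------------------------------

def build_reference_table(
    curves: SmoothedCurveSet,
    sd_pair: SdCurvePair,
    spec: CurveSpec,
    enforce: str = "increasing",
) -> ReferenceTable:
    """Evaluate all curves on the integer grid into a validated table.

    As a final deterministic guard (identity on well-behaved input) the
    percentile values are projected to be monotone in the index and
    strictly ordered across levels before validation.
    """
    grid = curves.grid.astype(float)
    mat = np.column_stack([curves.curves[lv](grid) for lv in curves.levels])
    if not np.all(np.isfinite(mat)):
        raise InvariantError("non-finite percentile values on the grid")
    if enforce == "increasing":
        iso = IsotonicRegression(increasing=True)
        for j in range(mat.shape[1]):
            mat[:, j] = iso.fit_transform(grid, mat[:, j])
    mat = np.sort(mat, axis=1)
    for j in range(1, mat.shape[1]):
        mat[:, j] = np.maximum(mat[:, j], mat[:, j - 1] + _LADDER_EPS)

    mean = sd_pair.mean_curve(grid)
    sd_u = np.maximum(sd_pair.sd_upper_curve(grid), 1e-6)
    sd_l = np.maximum(sd_pair.sd_lower_curve(grid), 1e-6)
    data = pd.DataFrame({"index": grid, "mean": mean,
                         "sd_upper": sd_u, "sd_lower": sd_l})
    for j, lv in enumerate(curves.levels):
        data[f"p{lv}"] = mat[:, j]
    table = ReferenceTable(spec.sex, spec.measure, spec.index_kind, data)
    table.validate()
    return table


def build_curve(
    cohort,
    spec: CurveSpec,
    config: BuilderConfig = BuilderConfig(),
    birth_reference: ReferenceTable | None = None,
    unknown_ga_fallback: bool = False,
) -> dict:
    """Full per-curve pipeline on a cleaned cohort.

    Eligibility selection, then for weight a single-pass >3 SD
    exclusion against a preliminary mean / asymmetric-SD fit of the
    eligible points themselves, then windowed percentiles, smoothing
    (stratified for weight), monotonicity and non-crossing enforcement,
    the quadratic tail refit, and final mean / SD curves.  Returns a
    dict with the table and all intermediates plus stage counts.
    """
    from .zscores import exclude_extreme_weights

    eligible = select_for_curve(cohort, spec, birth_reference, unknown_ga_fallback)
    counts = {"eligible": eligible.n_included(), "excluded": eligible.n_excluded()}
    pts = eligible.points
    excluded_extreme = pd.DataFrame()

    if spec.measure == "weight":
        pre_mean = estimate_mean_curve(pts, spec, config)
        pre_sd = estimate_asymmetric_sd(pts, pre_mean, spec, config)
        pts, excluded_extreme = exclude_extreme_weights(
            pts, pre_sd, threshold=config.exclusion_threshold, spec=spec)
        counts["extreme_weight_excluded"] = len(excluded_extreme)

    emp = empirical_percentiles(pts, spec, config)
    if spec.measure == "weight":
        cs = smooth_weight_stratified(emp, config, domain=spec.age_domain)
    else:
        cs = smooth_percentiles(emp, config, domain=spec.age_domain)
        cs = enforce_monotone(cs)

    refit_dom = config.refit_domains.get(spec.measure)
    if refit_dom is not None:
        lo, hi = spec.age_domain
        if refit_dom[0] >= lo and refit_dom[1] <= hi:
            cs = polynomial_refit(cs, refit_dom)

    mean_curve = estimate_mean_curve(pts, spec, config)
    sd_pair = estimate_asymmetric_sd(
        pts, mean_curve, spec, config, symmetric=spec.measure != "weight")
    table = build_reference_table(cs, sd_pair, spec)
    counts["table_rows"] = len(table.data)

    return {"eligible": eligible, "points": pts, "emp": emp, "curves": cs,
            "mean_curve": mean_curve, "sd_pair": sd_pair, "table": table,
            "excluded_extreme": excluded_extreme, "counts": counts}
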
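"""Synthetic longitudinal achondroplasia-like cohort generator.

Emulates the statistical structure the pipeline assumes — mixed
cross-sectional / longitudinal visit schedules denser at young ages,
monotone decelerating stature growth, right-skewed (log-normal-style)
weight, strong within-subject tracking, a premature fraction, subjects
censored by growth-modulating treatment, neurosurgical events, and
transcription errors injected at recorded positions — together with a
truth ledger (closed-form centile functions, per-subject effects,
error positions, censoring ages) so that every pipeline stage can be
tested against known ground truth.

Model
-----
For measure median ``m(a) = A - B * exp(-C * a**D)`` (age ``a`` in
months) and a spread function, each value is

* stature / head circumference:  ``v = m(a) + s(a) * z``
* weight:                        ``v = m(a) * exp(sigma(a) * z)``

with ``s(a) = s0 + s1 * m(a)`` and ``sigma(a) = sigma0 + sigma1 * a``
(the weight skew parameters), and ``z = a_w * U_i + b_w * E_ij`` a
tracking-dominated mix of a per-subject effect ``U_i`` and visit-level
noise ``E_ij``, both standard truncated normals (bounded at +/- 2.5)
so that plausible trajectories respect the data-cleaning screens by
construction; ``a_w**2 + b_w**2 = 1`` keeps the marginal spread unit.
The marginal quantile of ``z`` is computed exactly (to grid tolerance)
by numerical convolution of the two truncated-normal densities, which
makes :func:`true_percentile` a closed-form-grade oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .errors import ConfigurationError
from .records import Cohort, DAYS_PER_MONTH, DECADES

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_cohort",
           "true_percentile", "true_median"]

Z_BOUND = 2.5  # truncation of both noise components, in SD units

#: median-curve constants (A, B, C, D) per (sex, measure)
GROWTH_PARAMS = {
    ("male", "stature"): (127.0, 80.0, 0.0105, 1.0),
    ("female", "stature"): (120.0, 74.0, 0.0105, 1.0),
    ("male", "weight"): (52.0, 48.7, 0.016, 0.8),
    ("female", "weight"): (48.0, 44.9, 0.016, 0.8),
    ("male", "head_circumference"): (55.0, 18.5, 0.04, 1.0),
    ("female", "head_circumference"): (54.0, 18.0, 0.042, 1.0),
}

#: spread: (s0, s1) with s(a) = s0 + s1 * m(a) for the additive measures;
#: for weight the pair is (sigma0, sigma1) with sigma(a) = sigma0 + sigma1 * a
SPREAD_PARAMS = {
    ("male", "stature"): (0.37, 0.030),
    ("female", "stature"): (0.35, 0.030),
    ("male", "weight"): (0.085, 0.0001),
    ("female", "weight"): (0.085, 0.0001),
    ("male", "head_circumference"): (0.55, 0.020),
    ("female", "head_circumference"): (0.53, 0.020),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator; the seed fixes the full stream."""

    n_subjects: int = 1000
    seed: int = 0
    male_fraction: float = 0.51
    premature_fraction: float = 0.117
    unknown_ga_fraction: float = 0.12
    treatment_fraction: float = 0.05
    treatment_age_months: tuple = (48.0, 180.0)
    neuro_fraction: float = 0.18
    birth_entry_prob: float = 0.80
    followup_mean_months: float = 60.0
    complete_followup_prob: float = 0.80  # fully abstracted charts
    max_age_months: float = 240.0
    hc_max_age_months: float = 72.0
    #: visit gap ranges (months) by age band: <12 mo, 12-36 mo, >36 mo
    gap_ranges: tuple = ((1.0, 2.5), (2.0, 4.0), (4.0, 6.0))
    visit_noise_sd: float = 0.35    # b_w; subject effect is sqrt(1 - b_w**2)
    noise_corr_time_months: float = 84.0  # AR(1) time constant of visit noise
    premature_deficit_per_week: float = 0.35  # z-units at birth, decaying
    error_rate: float = 0.003
    decade_probs: tuple = (0.10, 0.15, 0.20, 0.25, 0.30)  # aligned with DECADES
    decade_effects: dict = field(default_factory=dict)    # decade -> weight z shift
    post_neuro_hc_shift: float = 0.0   # cm added to HC after a neuro event
    growth_params: dict = field(default_factory=lambda: dict(GROWTH_PARAMS))
    spread_params: dict = field(default_factory=lambda: dict(SPREAD_PARAMS))

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for name in ("male_fraction", "premature_fraction", "unknown_ga_fraction",
                     "treatment_fraction", "neuro_fraction", "birth_entry_prob",
                     "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.visit_noise_sd < 1.0:
            raise ConfigurationError("visit_noise_sd must be in (0, 1)")
        if abs(sum(self.decade_probs) - 1.0) > 1e-9:
            raise ConfigurationError("decade_probs must sum to 1")

    @property
    def subject_effect_sd(self) -> float:
        return float(np.sqrt(1.0 - self.visit_noise_sd**2))


@dataclass
class SyntheticTruth:
    """Ground truth: centile params, subject effects, errors, censoring."""

    config: SimulationConfig
    subject_effects: pd.DataFrame   # subject_id, u (truncated-normal effect)
    errors: pd.DataFrame            # point_row, subject_id, measure, age_days,
                                    # original_value, corrupted_value, kind
    censor_ages: pd.DataFrame       # subject_id, first_treatment_age_days


# ----------------------------------------------------------------------
# true centile machinery
# ----------------------------------------------------------------------

def _median(params, age_months):
    A, B, C, D = params
    a = np.asarray(age_months, dtype=float)
    return A - B * np.exp(-C * np.power(a, D))


def _spread(measure, spread, params, age_months):
    a = np.asarray(age_months, dtype=float)
    p0, p1 = spread
    if measure == "weight":
        return p0 + p1 * a          # log-scale SD
    return p0 + p1 * _median(params, a)


@lru_cache(maxsize=8)
def _z_quantile_table(a_w: float, b_w: float, bound: float = Z_BOUND):
    """Exact (to grid tolerance) quantile table of a_w*U + b_w*E.

    U, E independent standard truncated normals on [-bound, bound];
    the density of the sum is a numerical convolution on a fine grid.
    """
    dz = 5e-4
    ga = np.arange(-bound * a_w, bound * a_w + dz, dz)
    gb = np.arange(-bound * b_w, bound * b_w + dz, dz)
    fa = truncnorm.pdf(ga / a_w, -bound, bound) / a_w
    fb = truncnorm.pdf(gb / b_w, -bound, bound) / b_w
    f = np.convolve(fa, fb) * dz
    z = np.arange(f.size) * dz + (ga[0] + gb[0])
    # midpoint rule keeps the CDF symmetric, so the median maps to 0 exactly
    cdf = (np.cumsum(f) - 0.5 * f) * dz
    cdf /= (np.sum(f) * dz)
    return z, cdf


def _z_quantile(p, a_w: float, b_w: float) -> np.ndarray:
    z, cdf = _z_quantile_table(round(a_w, 12), round(b_w, 12))
    p = np.asarray(p, dtype=float)
    # the noise law is symmetric: antisymmetrising the lookup removes any
    # residual grid discretisation bias
    return 0.5 * (np.interp(p, cdf, z) - np.interp(1.0 - p, cdf, z))


def true_percentile(config: SimulationConfig, sex: str, measure: str,
                    age_months, level: float):
    """The generator's true centile — the oracle for recovery tests."""
    if not 0.0 < level < 100.0:
        raise ConfigurationError("level must be in (0, 100)")
    params = config.growth_params[(sex, measure)]
    spread = config.spread_params[(sex, measure)]
    b_w = config.visit_noise_sd
    zq = _z_quantile(level / 100.0, config.subject_effect_sd, b_w)
    m = _median(params, age_months)
    s = _spread(measure, spread, params, age_months)
    if measure == "weight":
        return m * np.exp(s * zq)
    return m + s * zq


def true_median(config: SimulationConfig, sex: str, measure: str, age_months):
    return _median(config.growth_params[(sex, measure)], age_months)


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _truncate(x: np.ndarray, bound: float = Z_BOUND) -> np.ndarray:
    """Map standard normals to standard truncated normals (exact marginal)."""
    return truncnorm.ppf(norm.cdf(x), -bound, bound)


def _visit_ages(rng, cfg: SimulationConfig) -> np.ndarray:
    """Renewal-process visit schedule, denser at young ages."""
    if rng.random() < cfg.birth_entry_prob:
        entry = 0.0
    else:
        entry = rng.uniform(0.0, 216.0)
    if rng.random() < cfg.complete_followup_prob:
        followup = cfg.max_age_months
    else:
        followup = rng.exponential(cfg.followup_mean_months)
    end = min(entry + followup, cfg.max_age_months)
    ages = [entry]
    t = entry
    (g1, g2, g3) = cfg.gap_ranges
    while True:
        lo, hi = g1 if t < 12.0 else (g2 if t < 36.0 else g3)
        t = t + rng.uniform(lo, hi)
        if t > end:
            break
        ages.append(t)
    return np.asarray(ages)


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, SyntheticTruth]:
    """Generate a cohort plus its truth ledger, reproducibly from the seed.

    Per subject: sex, gestational age (term / premature / unknown),
    birth decade and a tracking effect are drawn; visit ages follow an
    age-banded renewal process; values follow the truth model with
    visit-level truncated noise.  Premature subjects carry a birth-size
    deficit decaying over infancy; limb lengthening adds an abrupt
    stature gain after the event (deliberately flaggable — the screens
    are meant to catch it), growth hormone a gradual one, trial
    participation a weight shift; transcription errors are injected at
    recorded positions with magnitudes far beyond the cleaning
    thresholds (weight x10, stature +25 cm, HC +15 cm).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config
    b_w = cfg.visit_noise_sd
    a_w = cfg.subject_effect_sd

    subj_rows, point_rows, event_rows, effect_rows, censor_rows = [], [], [], [], []

    for i in range(cfg.n_subjects):
        sid = f"S{i:05d}"
        sex = "male" if rng.random() < cfg.male_fraction else "female"
        decade = DECADES[rng.choice(len(DECADES), p=cfg.decade_probs)]
        r = rng.random()
        if r < cfg.premature_fraction:
            ga_true = rng.uniform(28.0, 36.5)
            ga_recorded = ga_true
        elif r < cfg.premature_fraction + cfg.unknown_ga_fraction:
            ga_true = rng.uniform(38.0, 41.0)
            ga_recorded = np.nan
        else:
            ga_true = rng.uniform(37.0, 42.0)
            ga_recorded = ga_true

        u = float(_truncate(rng.standard_normal()))
        effect_rows.append({"subject_id": sid, "u": u})

        treat_kind, treat_age_days = None, np.inf
        if rng.random() < cfg.treatment_fraction:
            treat_kind = ("limb_lengthening", "growth_hormone",
                          "pharma_trial")[rng.choice(3)]
            treat_age_m = rng.uniform(*cfg.treatment_age_months)
            treat_age_days = treat_age_m * DAYS_PER_MONTH
            event_rows.append({"subject_id": sid, "event_kind": treat_kind,
                               "age_days": treat_age_days})
            censor_rows.append({"subject_id": sid,
                                "first_treatment_age_days": treat_age_days})
        neuro_age_m = np.inf
        if rng.random() < cfg.neuro_fraction:
            neuro_kind = "cmd" if rng.random() < 0.6 else "shunt"
            neuro_age_m = float(np.clip(np.exp(rng.normal(np.log(12.0), 0.8)),
                                        1.0, 72.0))
            event_rows.append({"subject_id": sid, "event_kind": neuro_kind,
                               "age_days": neuro_age_m * DAYS_PER_MONTH})

        subj_rows.append({"subject_id": sid, "sex": sex,
                          "gestational_age_weeks": ga_recorded,
                          "birth_decade": decade})

        ages = _visit_ages(rng, cfg)
        deficit = (cfg.premature_deficit_per_week * (37.0 - ga_true)
                   * np.exp(-ages / 9.0)) if ga_true < 37.0 else 0.0
        treat_age_m = treat_age_days / DAYS_PER_MONTH

        for measure in ("stature", "weight", "head_circumference"):
            if measure == "head_circumference":
                keep = ages <= cfg.hc_max_age_months
            else:
                keep = np.ones(ages.shape, bool)
            a = ages[keep]
            if a.size == 0:
                continue
            # slowly varying visit-level noise: stationary Gaussian AR(1)
            # over the visit ages, mapped to an exact truncated-normal
            # marginal; slow drift keeps consecutive-visit changes small
            g = np.empty(a.size)
            g[0] = rng.standard_normal()
            if a.size > 1:
                phi = np.exp(-np.diff(a) / cfg.noise_corr_time_months)
                innov = rng.standard_normal(a.size - 1)
                for j in range(1, a.size):
                    g[j] = phi[j - 1] * g[j - 1] + np.sqrt(
                        1.0 - phi[j - 1]**2) * innov[j - 1]
            e = _truncate(g)
            z = a_w * u + b_w * e
            if np.ndim(deficit):
                z = z - np.asarray(deficit)[keep]
            params = cfg.growth_params[(sex, measure)]
            spread = cfg.spread_params[(sex, measure)]
            m = _median(params, a)
            s = _spread(measure, spread, params, a)
            if measure == "weight":
                z = z + cfg.decade_effects.get(decade, 0.0)
                if treat_kind == "pharma_trial":
                    ramp = np.clip((a - treat_age_m) / 6.0, 0.0, 1.0)
                    z = z + 0.2 * ramp
                v = m * np.exp(s * z)
            else:
                v = m + s * z
                if measure == "stature":
                    if treat_kind == "limb_lengthening":
                        v = v + 6.0 * np.clip((a - treat_age_m) / 3.0, 0.0, 1.0)
                    elif treat_kind == "growth_hormone":
                        v = v + np.clip(0.15 * (a - treat_age_m), 0.0, 4.0)
                elif neuro_age_m < np.inf and cfg.post_neuro_hc_shift:
                    v = v + cfg.post_neuro_hc_shift * (a >= neuro_age_m)
            for aj, vj in zip(a, v):
                point_rows.append({
                    "subject_id": sid, "measure": measure,
                    "age_days": float(aj * DAYS_PER_MONTH),
                    "value": float(vj),
                    "position": ((("supine" if aj < 24.0 else "standing")
                                  if measure == "stature" else None)),
                })

    points = pd.DataFrame(point_rows,
                          columns=["subject_id", "measure", "age_days",
                                   "value", "position"])
    subjects = pd.DataFrame(subj_rows)
    events = pd.DataFrame(event_rows,
                          columns=["subject_id", "event_kind", "age_days"])

    # transcription errors at recorded positions
    err_rows = []
    if cfg.error_rate > 0 and len(points):
        hit = rng.random(len(points)) < cfg.error_rate
        for row in np.flatnonzero(hit):
            measure = points.at[row, "measure"]
            orig = float(points.at[row, "value"])
            if measure == "weight":
                bad, kind = orig * 10.0, "weight_x10"
            elif measure == "stature":
                bad, kind = orig + 25.0, "stature_plus25"
            else:
                bad, kind = orig + 15.0, "hc_plus15"
            points.at[row, "value"] = bad
            err_rows.append({"point_row": int(row),
                             "subject_id": points.at[row, "subject_id"],
                             "measure": measure,
                             "age_days": float(points.at[row, "age_days"]),
                             "original_value": orig, "corrupted_value": bad,
                             "kind": kind})
    errors = pd.DataFrame(err_rows,
                          columns=["point_row", "subject_id", "measure",
                                   "age_days", "original_value",
                                   "corrupted_value", "kind"])

    cohort = Cohort(subjects, points, events)
    cohort.validate()
    truth = SyntheticTruth(
        config=cfg,
        subject_effects=pd.DataFrame(effect_rows),
        errors=errors,
        censor_ages=pd.DataFrame(censor_rows,
                                 columns=["subject_id",
                                          "first_treatment_age_days"]),
    )
    return cohort, truth
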
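# Methods

## The reference-construction model

Growth references here are *empirical-quantile-first*: no parametric
family (no Box–Cox/LMS transform) is imposed on the age-specific
measurement distribution. For each sex and measure, the pipeline

1. computes raw percentiles (5/25/50/75/95) at each integer month `g`
   from all eligible values within an age window `|a − g| ≤ h(g)`,
   where `h` is 0.5 months through the first year, 1 month over
   1–3 years and 3 months over 3–18 years (windows truncated at the
   domain edges, never reflected); on height grids the window is a
   fixed ±1 cm. Quantiles use linear interpolation of the empirical
   distribution (numpy's default, the "type 7" convention), and the
   test-suite oracle uses the identical convention so agreement is
   exact, not approximate. Windows holding fewer than `min_window_n =
   10` values yield missing estimates that the smoother bridges.
2. smooths each percentile series with a penalized cubic spline:
   cubic B-spline basis on equally spaced interior knots (20 for a
   0–216-month domain, 8/10 for the weight strata, 10 for height
   grids), a second-order difference penalty on the coefficients, and
   a smoothing parameter chosen by generalized cross-validation on a
   fixed log-spaced grid (49 points, 1e-4…1e8; overridable). The
   penalty null space contains straight lines, so constants and linear
   trends are reproduced exactly at any penalty.
3. enforces shape. Weight is fitted separately on 0–36 and 36–216
   months (its skew grows with age) and the two fits are blended by a
   linear cross-fade over 34–38 months, which makes the seam exactly
   continuous. If a percentile curve decreases anywhere on the integer
   grid, the knot count is reduced stepwise (to a floor of 4); if no
   knot count achieves monotonicity, the *original best-fitting* curve
   is replaced by its isotonic (pool-adjacent-violators) projection —
   projecting the best fit rather than the floor-knot fit keeps
   fidelity where the curve was already monotone. Levels are then made
   non-crossing by sorting values at each grid point and re-smoothing
   once; should any violation survive, the table assembly applies a
   final deterministic guard (per-level isotonic projection, pointwise
   sort, and a 1e-4 strictness ladder) that is the identity on
   well-behaved input. Monotone interpolants use PCHIP, which
   preserves monotone data.
4. refits the sparse tail with a quadratic: spline predictions on the
   integer grid over 13–18 years (stature, weight) or 4–5 years (head
   circumference) are least-squares fit by a second-degree polynomial
   that replaces the curve there, with a one-grid-unit linear
   cross-fade below the edge so no step is introduced.

Mean curves are penalized-spline regressions on the raw points (not on
windowed summaries). SD curves split the points at the mean curve
(ties to the lower side): at each month the upper (lower) empirical SD
is the RMS deviation from the mean curve over upper (lower) values
within ±2 months, smoothed by a penalized spline and floored at
10⁻³ of the mean. RMS-about-the-mean-curve (rather than about the
subset's own mean) is chosen because it reduces to σ under symmetric
noise — `E[(X−μ)² | X>μ] = σ²` — which makes ±2 thresholds comparable
across sides; the subset-mean convention is available via
`sd_center="subset_mean"`. The ±2-month SD window is kept fixed at all
ages even though percentile windows widen to ±3 months past age 3;
the two estimators are deliberately independent.

Z-scores interpolate mean and both SDs linearly between monthly rows
and divide by the side-specific SD, so value→z→value is exactly
invertible per side. Weight points with |z| > 3 against a reference
fitted to the *pre-exclusion* eligible points are excluded in a single
pass (no refit-and-repeat) before the weight percentile curves are
built; under Gaussian noise this removes ≈ 2Φ(−3) ≈ 0.27% of points.

## Eligibility rules and their order

Sex and measure filters define the input universe; the ledger then
applies, first match wins: (1) premature (< 37.0 weeks gestation) and
age < 24.0 months; (2) unknown gestational age and age < 24 months,
unless the opt-in fallback finds a birth measurement (age ≤ 3 days)
above −2 SD on a supplied condition-specific birth reference;
(3) at/after the earliest limb-lengthening / growth-hormone / trial
event; (4) for head circumference with post-neurosurgery points
disabled, at/after the earliest decompression/shunt event; (5) outside
the curve domain. Censoring at `age ≥ event age` is the conservative
reading (the event-day measurement is excluded). Jump screens are
re-evaluated after drops until a fixed point, because removing a point
creates new adjacencies; the hard caps cannot re-fire.

## What the synthetic generator emulates — and what it does not

Each subject draws sex (51% male), a birth decade, gestational age
(11.7% premature, 12% unknown-but-term), optional treatment (5%,
uniform kind, at 4–15 years) and neurosurgery (18%, log-normal around
12 months). Visits follow an age-banded renewal process (gaps
uniform on 1–2.5 / 2–4 / 4–6 months by age band) from an entry age
(80% enrolled at birth, otherwise uniform); 80% of charts are
abstracted over the full age range, the rest for an exponential
(mean 60 months) span. The follow-up is deliberately predominantly
longitudinal: windowed tail percentiles are limited by the number of
*subjects* per age region, and the generator's own recovery contract
(p5/p50/p95 within 3% at n = 800) requires most subjects to cover most
of the domain.

Values follow `m(a) = A − B·exp(−C·a^D)` medians with affine spreads;
weight is generated on the log scale (`v = m·exp(σ(a)·z)`, σ from
0.085 to ~0.11 across childhood), which yields the right skew and
`sd_upper > sd_lower` structurally. The noise `z` mixes a constant
subject effect (sd ≈ 0.94) with a slowly varying AR(1) visit component
(sd 0.35, correlation time 84 months), both mapped to exact truncated
normals (±2.5). Bounded noise plus slow drift means untreated,
error-free trajectories respect every cleaning screen by construction
(worst-case margins ≥ ~4.5 visit-noise SDs) — so a zero-flag run on a
clean cohort is informative, not vacuous. Limb lengthening, by
contrast, adds an abrupt +6 cm over three months *on purpose*: it is
real signal the screens should catch, and those points are censored
from curves anyway. Growth constants are mild compromises: infancy
velocity is slower than clinical reality so that genuine growth
between adjacent visits never trips the jump thresholds that the
cleaning module must apply verbatim.

The marginal quantile of the two-component truncated noise has no
elementary closed form; `true_percentile` computes it by numerical
convolution of the two densities on a 5·10⁻⁴ grid with a symmetrised
lookup — exact to well below every tolerance used in testing.

Injected transcription errors (rate 0.003) are gross by design
(weight ×10, stature +25 cm, HC +15 cm): the recall target concerns
errors beyond the cleaning thresholds, and subtler errors are
indistinguishable from noise by any threshold rule. What the generator
does **not** emulate: real measurement-protocol differences
(supine-vs-standing offsets are labels only), secular drift (zero by
default; injectable for power tests), treatment efficacy, site effects,
and the heavier true weight CV of clinical cohorts. Passing recovery
tests therefore demonstrates correctness of the estimator machinery
under a faithful-in-structure model, not clinical validity of any
specific synthetic curve.

## Numerical choices and degenerate inputs

- Age is stored in days; months = days / 30.4375 (mean Gregorian
  month) so grids are calendar-independent.
- "6 months" is 182 days; "< 15 days" is strict; averaging uses chain
  merging (transitive closure), is idempotent in practice and never
  increases the point count.
- The weight-jump screen checks *any* pair closer than 182 days (the
  rule names no adjacency); stature/HC jump screens check adjacent
  pairs. The stature screen is direction-free (|Δ|).
- Spline solves add a 10⁻⁹ ridge for conditioning; GCV guards its
  denominator at 10⁻⁸. Evaluation clamps to the fitted domain (no
  extrapolation); Z-scoring outside a table's grid raises rather than
  extrapolates.
- Empty windows warn and yield empty sets; fewer than 4 non-missing
  grid points, or fewer than 20 points for a mean curve, raise
  `FitError` naming the level.
- Default problem sizes in tests (cohorts of 120–800 subjects; 10,000
  for secular-trend nulls, where between-decade medians must be stable
  to < 0.2 z) were chosen so each check has adequate statistical power
  at comfortable runtime.

## Known limitations

- The pipeline resolves every flag by dropping (an automated stand-in
  for the chart review it cannot perform); with single-visit subjects
  a gross error can be undetectable by any within-subject rule and
  will slightly inflate raw summaries such as birth-weight SD.
- The female weight-for-height domain defaults to 50–134 cm (the range
  with adequate data), configurable; the male domain is 50–140 cm.
- GCV under within-subject correlation tends to undersmooth; the knot
  caps and the quadratic tail refit are the pragmatic guards. Remaining
  recovery error at tail percentiles is dominated by between-subject
  sampling noise, not smoothing bias.
- The unknown-gestational-age birth fallback compares the birth value
  of the measure being curved; cohorts without birth measurements
  (the common case) never exercise it.
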
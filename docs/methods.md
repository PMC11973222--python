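# Methods

## Model and procedure

The quantity of interest is the precision of a percentile D_p (p ∈ {10, 25,
50, 75, 90}) of the number-based distribution of a particle measurand, as
limited purely by the number of particles measured.  Treating the largest
available dataset (N_tot particles) as the best estimate of the population,
the sampling distribution of D_p at a smaller count N is emulated by drawing
subsets of N particles **with replacement** and recomputing the percentiles.
With `reps` repetitions the spread is summarized as the sample standard
deviation σ (divisor reps − 1) and reported as the relative expanded
uncertainty U_N = 2σ/D̄ (coverage factor k = 2).

Asymptotically the standard error of a sample quantile is
√(p(1−p)/N)/f(x_p), so U_N scales as 1/√N and log U_N is linear in log N
with slope −1/2.  The minimum count N_m for a target U_N is obtained by
inverting the ordinary-least-squares line of log10 U_N on log10 N — robust
to Monte-Carlo scatter at large N — with a cross-validated smoothing spline
(isotonic-corrected to non-increasing) as an alternative inversion route.
Because subsets are drawn with replacement from an empirical distribution,
U_N estimates at N approaching N_tot remain meaningful but increasingly
reflect that single dataset's realized histogram rather than the underlying
population; comparisons with the asymptotic formula are therefore restricted
to N ≤ N_tot/10.

### Quantile convention

All percentiles use linear interpolation between closest order statistics at
fractional rank 1 + (n − 1)p (numpy's `linear` method).  The choice is
irrelevant beyond n ≈ 100 but is fixed and used everywhere — summaries and
bootstrap alike — for internal consistency.

### Uncertainty budget

From a validation design (≥2 days × replicates), per subset size N and per
simulation repetition one subset is drawn from every dataset and the
percentile computed; a one-way variance decomposition with day as grouping
factor gives within-day and between-day mean squares, combined as
u_IP = √(s_between² + MS_within)/D̄ with s_between² = max(0, (MS_b −
MS_w)/r̄), r̄ the harmonic-mean number of replicates per day (negative
components clipped to zero).  Trueness versus a certified value uses the
standard CRM bias combination u_tr = √(Δ² + u_cert² + se_mean²)/certified;
without a certified value a fixed relative u_tr must be supplied explicitly.
Calibration enters as a constant relative u_cal.  The total is
U_cx = 2√(u_IP² + u_tr² + u_cal²).

N_opt is the breakpoint of a continuous two-segment least-squares fit in
(log10 N, log10 U_cx), found by exhaustive search over interior grid
positions with a 10× sub-grid refinement, ties broken toward the smaller
count (conservative for measurement cost).  When the two-segment model
improves the single-line SSE by less than 5% the breakpoint is flagged
unidentifiable rather than reported.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `reps` | 500 | bootstrap repetitions per subset size; the σ estimate then has ~3% relative chi-square width, small against the effects measured |
| N grid | 30 log-spaced integers, 10 → N_tot | covers the full range with uniform density in log N, where the fit is performed |
| grid floor | 10 particles | percentiles of smaller subsets are dominated by interpolation artefacts |
| k | 2 | expanded uncertainty at ≈95% confidence throughout |
| `u_target` | fraction internally, percent at the CLI | e.g. 0.05 = 5% |

Reproducibility: every stochastic operation takes one master seed; one RNG
substream per subset size N (derived as `SeedSequence([seed, N])`) makes
results bit-identical for identical inputs and lets an N grid be extended
without changing the draws at already-computed sizes.  (Extending `reps`
does reshuffle; that trade-off favours vectorized drawing.)

## Synthetic populations

The generators emulate the realistic material spectrum — narrow colloids,
right-skewed powders, multimodal and rod-like materials — as distribution
families matched on the two parameters that drive count-limited precision:
the median and IQR% = 100·(D75 − D25)/D50.

* lognormal: shape from the closed inversion s = asinh(IQR%/200)/z₀.₇₅
  (quartiles sit at median·exp(±z₀.₇₅ s), hence IQR% = 200·sinh(z₀.₇₅ s));
* gamma / weibull: shape solved numerically so the distribution's own IQR%
  matches (IQR% depends only on the shape parameter); scale matches the
  median; these provide right- and left-skewed cases;
* bimodal mixture: two lognormal components (weight, separation); matched on
  the overall median only — a target IQR% is not enforced for mixtures;
* rod: lognormal widths (fmin = micd), aspect-ratio draws with AR ≥ 1
  giving fmax = width·AR, and ECD from a spherocylinder projected area
  A = W(L − W) + πW²/4, ECD = √(4A/π) — any consistent convex-particle
  convention would do and this one reduces exactly to a disc at L = W.
  A degenerate `iqr_pct = 0` produces constant populations for exact tests.

Replicate designs multiply all sizes of a day's datasets by a lognormal
day factor with mean 1 and the prescribed CV (multiplicative, so sizes stay
positive) and by a global bias factor.  The realized day factors are stored
as ground truth alongside the nominal CV.

What the generators do **not** emulate: segmentation artefacts (erroneously
merged particles that broaden real distributions), magnification effects,
within-day preparation variability beyond counting noise, and any
correlation structure between measurands other than the rod geometry.
Passing tests therefore demonstrate the statistical machinery on clean
distributions matched to realistic medians/widths, not the image-analysis
pipeline upstream of the particle table.

## Statistical design of the validation checks

Two estimator-noise facts shape the tests:

* With 3 days, the realized between-day spread of one design is
  chi-square(2)-distributed around the nominal CV (±~50%).  Recovery checks
  of the day-effect CV and of a planted bias therefore average over
  independent design realizations (16 and 96 respectively), which isolates
  estimator bias from realization luck; a single-design comparison to the
  nominal CV would be uninformative.  Saturation of U_cx is instead checked
  against the floor implied by the *realized* day factors and bias, which is
  sharp for a single design.
* A single bootstrap U_N estimate at 500 repetitions carries ~3%
  chi-square noise plus, at N near N_tot/10, several percent of
  empirical-density noise from the one finite dataset.  Oracle-equivalence
  checks against the asymptotic quantile-SE formula therefore average over
  three independent populations, so that the 15% agreement band tests
  systematic correctness rather than single-realization scatter.

Problem sizes used throughout (populations of 20000 particles for precision
curves, 500 bootstrap repetitions, 1000–4000 particles per dataset in design
simulations) were chosen so that Monte-Carlo error is small against every
tolerance tested while full runs stay interactive.

## Numerical choices and degenerate inputs

* Zero-dispersion (constant) data: U_N is identically zero, the log-log fit
  is undefined, and a dedicated error carrying the all-zero U_N vector is
  raised rather than returning NaN slopes.
* N_m inversions already below target at the grid floor return 10 with an
  `at_grid_floor` flag; inversions beyond N_tot are permitted but flagged as
  extrapolation.
* Spline smoothing is selected by leave-one-out cross-validation in log-log
  space; the evaluated curve is post-corrected by a running minimum to be
  non-increasing, which also makes its inversion unique.
* Power-law fits are linear regressions in log space (scale-free residuals)
  rather than nonlinear least squares.
* Category boundaries are upper-inclusive; IQR% beyond the categorized range
  (80 size, 55 shape) yields an explicit out-of-range result, never a clamp.
  Shape-mode categories define ranges only — no guidance counts exist for
  them.
* Tables: rows with non-finite or non-positive sizes are dropped with a
  logged count; rows with fmax < fmin are an error with row numbers, since
  they indicate upstream segmentation faults that should not be silently
  repaired.

## Known limitations

* N_m and N_opt for specific real materials depend on their actual (often
  non-ideal) histograms; the surrogate families bound but do not reproduce
  material-specific values.
* The intermediate-precision and trueness estimators follow standard
  method-validation ANOVA/CRM practice; laboratories using different
  combination rules will get numerically different budgets.
* The u_IP estimator assumes a balanced-enough day/replicate layout
  (harmonic-mean replicates per day); strongly unbalanced designs are
  accepted but the variance decomposition is then approximate.
* Sampling bias (deposition on the grid) and image-analysis bias are outside
  the model: U_N and U_cx quantify precision and validated trueness, not
  those systematic effects.
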
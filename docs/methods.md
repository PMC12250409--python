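# Methods

## The calibration model

Let `PE_i(x) = postop_i − f_i(x)` be eye *i*'s prediction error when the
formula is evaluated at lens constant *x*, and `MPE(x)` its cohort mean.
The method assumes `f_i` is (locally) affine in the constant over the
working range, with a negative per-eye slope `s_i`: raising the constant
makes the predicted refraction more myopic, so `MPE(x)` is increasing in
*x* with slope `−mean(s_i) ≈ 0.7–0.8 D` per constant unit.  Measuring
`y1 = MPE(x1)` and `y2 = MPE(x2)` at two constants determines the line,
and the optimized constant is its exact zero,

    x_opt = x2 − y2 (x2 − x1) / (y2 − y1).

The root is closed-form — no iterative goal-seeking and no convergence
tolerance — and invariant to swapping the anchors.  A root outside
`[x1, x2]` is expected in practice (published optima sit ~1–2 anchor gaps
above both anchors) and is only *flagged*; a root more than 2 anchor gaps
beyond the nearest anchor additionally warns, since that usually means a
data problem rather than a miscalibrated lens.

Two degenerate inputs are handled explicitly: `y1 = y2 ≠ 0` has no root
(error), and `y1 = y2 = 0` makes every constant a root (returns `x2` with
a warning).

## Per-case correction

**Method-LI** carries each eye's prediction pair along its own line:
`y'_i = y2'_i + (y2'_i − y1'_i)(x_opt − x2)/(x2 − x1)`.  Since the mean of
the interpolated predictions is itself linear in *x* and `x_opt` zeroes the
mean-error line, the corrected cohort MPE is zero as an algebraic
identity (float round-off only; asserted at 1e−9 D).  **Method-S**
subtracts the cohort MPE from every PE (equivalently adds it to every
prediction at the reference anchor, default the higher one): exact zero
mean, dispersion untouched.

When `f_i` is exactly affine, Method-LI equals `f_i(x_opt)` per case —
corrected values coincide with recomputed "actual values".  When `f_i`
bends (in real data: short and long eyes), Method-LI errs by the
interpolation residual `−c_i (x_opt − x1)(x_opt − x2)` while Method-S errs
by a case-dependent amount that the single cohort shift cannot absorb;
this asymmetry is what the comparison harness is for.

## Accuracy panel

Per cell: MPE, MAE, MedAE (even *n*: mean of the two central order
statistics), sample SD of the APE (n−1 denominator), SE = SD/√n, 95% CI
as MAE ± 1.96·SE (the normal multiplier reproduces the published interval
arithmetic at n = 188), and the fraction of eyes with APE below 0.25 D
and 0.50 D.  Rates use a strict `<` by default with an `inclusive_rates`
toggle, since published tables are ambiguous exactly at the boundary.
All arithmetic is full precision; presentation rounding (half-up;
constants 3 dp, refraction statistics 3 dp, SE 4 dp, rates 0.1%) lives
only in the report layer.

## Comparison harness

APE columns for k aligned conditions form an n × k repeated-measures
matrix.  Shapiro–Wilk (delegated to scipy) gates each column at
α = 0.05: all normal → one-way within-subject ANOVA with paired-t post
hoc; otherwise Friedman (midranks, tie-corrected statistic
`(k−1)Σ(R_j − n(k+1)/2)² / (A − nk(k+1)²/4)` on χ²_{k−1}) with
Durbin–Conover post hoc `t = (R_j − R_l)/√(2n(A−B)/((n−1)(k−1)))` on
(n−1)(k−1) df.  Success indicators (APE under a threshold) are compared by
Cochran's Q with McNemar post hoc (uncorrected χ² by default; exact
two-sided binomial on request for small discordant counts).  Post hoc
pairs run only when the omnibus p < α, Bonferroni-adjusted over the
k(k−1)/2 pairs actually tested.

Numerical choices worth noting:

* APE values are rounded to 9 decimals before testing (configurable).
  Corrections that agree up to float round-off — Method-LI versus
  recomputed actual values under an affine law — must rank as exact ties,
  not as ~1e−13 "wins" with random signs.
* Degenerate inputs degrade explicitly rather than by NaN: identical
  columns give statistic 0 / p 1; zero error variance in the ANOVA is an
  infinite-F flag with p 0; an all-constant-rows binary matrix is a
  flagged Q = 0.  Perfectly consistent rankings make the Durbin–Conover
  variance zero; unequal-rank-sum pairs are then reported as maximally
  separated (p = 0), equal ones as null.
* Friedman, Cochran's Q, McNemar and the RM-ANOVA are implemented on
  scipy primitives (the post hoc needs the rank matrix, and the degenerate
  branches above are part of the contract); they are verified in the test
  suite against scipy.stats.friedmanchisquare, statsmodels and pingouin.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
eye optics: per eye, `f_i(x) = b_i + s_i(x − x_ref) + c_i(x − x_ref)²`
with `x_ref = x1`.  Defaults describe a realistic single-lens cataract
cohort: n = 188 eyes, axial length truncated-normal 23.8 ± 1.35 mm on
[20, 30]; slopes uniform on [−0.85, −0.65] D/unit (the range implied by
published anchor-MPE deltas over a 0.23-unit gap); target refraction at
the true constant N(−0.25, 0.25) D clipped to [−1.8, 0.8]; postoperative
noise SD 0.30 D; true zero-MPE constant 119.5 with anchors 119.1/119.33.
`quantize_2dp` rounds emitted predictions to 2 decimals, emulating
web-calculator output precision; `curvature_d_per_unit2` adds quadratic
curvature confined to eyes with AL < 22.5 or > 25.5 mm — a deliberately
simple stand-in mechanism for the short/long-eye nonlinearity whose
*consequences* are observed clinically, not a claim about how real
formulas behave.

Because the pseudo-formula is exposed, it doubles as the "actual value"
oracle: `recovery_experiment` repeatedly simulates, calibrates, and scores
the recovered constant against truth.  Under the affine generator the
estimator `x_opt = x_true − mean(ε)/mean(−s_i)` is linear in the noise,
hence exactly unbiased, with sampling SD `noise_sd/(|slope|·√n)` — the
delta-method prediction the consistency tests check (SD within 20% of
1/√n scaling across n = 50/200/1000; quantization keeps the actual-value
MPE two orders of magnitude inside the 0.01 D band).

What passing these tests does *not* show about real data: real formulas
are not affine over large constant shifts, biometry errors are not i.i.d.
Gaussian, and device/formula cells share eyes (correlated columns).  The
generator reproduces the repeated-measures layout and magnitudes, not
those dependencies.

## Problem sizes

Defaults were chosen so the whole validation is desk-scale: the suite's
Monte-Carlo blocks use 100–500 replicates of cohorts between 50 and 1000
eyes, which the package completes in seconds while leaving Monte-Carlo
error well below the asserted margins.

## Eligibility and strata

The study-protocol filters are reproduced exactly: CVA 20/40 or better
(logMAR ≤ 0.30, inclusive), one eye per patient with the better-CVA eye
kept and the right eye on an exact tie (the protocol is silent; a
deterministic tie-break is required for reproducibility), and strict
axial-length cutoffs (short < 22.5 mm, long > 25.5 mm, boundary eyes in
neither).

## Known limitations

Single-constant formulas only (no Haigis-style multi-constant refits);
spherical-equivalent refractions only (no toric/cylinder decomposition);
the MAE confidence interval is the normal approximation, not bootstrap;
the curvature mechanism in the generator is illustrative.
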
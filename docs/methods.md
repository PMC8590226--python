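# Methods

## The QEPS basis adopted here

The QEPS family is shape-invariant: population-level *shape constants* fix
the form of four basic functions, each rising from 0 to an asymptote of 1,
and six individual parameters scale and time them. The basis implemented in
`qeps_model` is

- `Q(t) = 2τ' − τ'²` with `τ' = clip((t − t_c)/(T_Q − t_c), 0, 1)` — a
  quadratic rise from conception `t_c` to a plateau of 1 at `T_Q`;
- `E(t) = 1 − exp(−(t − t_c)/τ_E)` — fast early saturation;
- `P(t) = logistic((t − θ_P)/σ_P)` — the pubertal spurt;
- `S(t) = logistic((t − θ_P − κ_S σ_P)/σ_P)` — a stop function sharing the
  pubertal tempo, delayed by `κ_S` tempo units.

The logistic basis gives closed forms for every landmark used downstream:
`Pmax = c_P`, `AgeP5 = θ_P − ln(19)·σ_P` (the age at 5% of Pmax, the
operational onset of the spurt), and exact time-shift equivariance of all
pubertal landmarks. The quadratic is written with the clipped argument, not
as a clipped value, because the function must plateau — stay at 1 — beyond
`T_Q` rather than decrease.

Shape-constant defaults (`T_Q` 17 y girls / 19 y boys, `τ_E` 0.6 y, `κ_S` 6,
`t_c` −0.75 y) are plausible auxological scales, configurable per sex; they
are not published estimates.

**TPHV.** The age at peak height velocity is found as the largest *interior*
local maximum of the analytic total velocity inside `θ_P ± 6σ_P`, refined by
bounded scalar maximisation to 1e-4 y. Total velocity declines monotonically
through childhood (the quadratic decelerates, the exponential is spent), so
when the search window reaches into childhood the global maximum sits at the
window edge; the spurt is by definition the interior acceleration peak. If
no interior peak exists the global argmax is returned.

## Fitting

`fit_height` estimates the six parameters per subject by bounded nonlinear
least squares. Since the model is linear in the four scales, each start
optimises only (θ_P, σ_P) with the scales profiled out by non-negative least
squares (variable projection), then polishes all six parameters jointly.
Starts are the fixed grid θ_P ∈ {9, 11, 13, 15} plus a moment-based guess
(age of maximal observed velocity between 8 and 16 y); the best final SSR
wins, ties broken toward the smallest θ_P, so fits are deterministic.
Coverage preconditions (≥ 6 height points spanning ages 2–16 with ≥ 2 points
after 13) reflect the six free parameters; one robustness pass zero-weights
observations with absolute studentised residual > 4 and refits.

**Height → weight.** Per sex, four coefficients α_X minimise the pooled sum
of squared differences between observed sqrt-weights and the linear
combination of each subject's scaled height components. The solve is
constrained non-negative: the stop coefficient is weakly identified (the
stop scale is small), and an unconstrained solve can return a slightly
negative α_S, which would produce invalid (negative-scale) weight parameter
sets. Construction-oracle tests confirm exact recovery when weights are
generated by the transform. Timing and tempo are copied from the height fit;
no six-parameter weight fit is ever performed — with weight's larger
residual variation it would overfit.

**WHF.** The weight–height factor is multiplicative on the whole sqrt-weight
curve, `(1 + WHF)·ŵ(t)`, with the closed form
`WHF = Σ ŵ·√w_obs / Σ ŵ² − 1`. Multiplicative (rather than additive) keeps
component additivity after scaling and cannot produce negative early-life
weights.

## References and SDS

References are built from *fitted* curves, not raw visits, which excludes
measurement error from the between-subject spread. Per grid point the
cross-subject median and SD (ddof 1) are taken in kg^0.5 (cm for height) for
three components: total, basic (Q+E−S) and puberty-specific (P). Grids are
0.1 y; chronological 4–20 y, puberty-aligned −4…+10 y around AgeP5.
Alignment always uses the *height*-derived AgeP5, also for weight curves, so
both traits share one biological clock. SDS is `(x − median)/SD` on the
reference scale with linear interpolation between grid points; out-of-range
queries raise rather than extrapolate, and an inverse SDS that would imply a
negative kg^0.5 value raises as well. Display bands in kg are derived by
squaring and never read back.

`assess_individual` implements the prospective workflow: given an externally
observed onset age (secondary sex characteristics, or height take-off), each
visit is re-expressed at `t′ = age − onset` and scored against the aligned
tables; visits outside the span are returned unscored.

## Subgroups and filters

Classification dimensions and bands: timing by TPHV deviation from the
sex-specific cohort mean (early < −1.5 y, average within ±0.25 y, late
> +1.5 y, strict inequalities, gaps unlabelled); stature at onset by height
SDS against the chronological reference (tall > +1.5, short < −1.5);
childhood BMI by the *peak* BMI SDS inside 3.5–7 y (girls) / 3.5–8 y (boys).
Group-mean SDS trajectories carry normal-approximation 95% CIs
(`mean ± 1.96·SD/√n`); groups with n < 2 are dropped with a warning.
Extreme-BMI exclusion removes a subject when any visit's BMI SDS leaves the
configured bounds (default ±3, a configuration value, not a published
criterion) against an empirical, cohort-derived, age-binned BMI reference.

## The synthetic cohort

The generator emulates a longitudinally followed school cohort: per-sex
log-normal scales (medians 98/52/17 cm girls, 103/55/22 cm boys for
c_Q/c_E/c_P; log-SDs 0.04/0.04/0.12), normal timing (11.0 ± 1.0 y girls,
13.0 ± 1.0 y boys), log-normal tempo (median 0.9 y, log-SD 0.15), normal
WHF (SD 0.05), transform coefficients chosen so birth, age-2, spurt-onset
and adult weights are auxologically plausible (e.g. an adult girl of about
167 cm and 60 kg). Visits follow a 25-point schedule from age 1 to 19 —
through adult height, so late maturers complete their spurt inside the
observation window — with 0.05 y jitter; noise is 0.5 cm for height and
0.05 kg^0.5 for weight, making weight relatively noisier than height as real
series are. One global seed; subject *i* draws from stream
`(seed, sex, i)`, so any subject is reproducible in isolation. Planted
subgroup effects shift the timing mean (optionally with a positive
half-normal margin so planted members land beyond a classification band
edge rather than on it), scale the basic or pubertal components, or shift
the WHF.

What the generator does *not* emulate: secular trends, parental heights,
correlated component scales, skew or heteroscedastic measurement error, and
real biological coupling between body composition and pubertal timing.
Passing recovery and subgroup tests therefore demonstrates that the
*pipeline machinery* is correct and calibrated under its own assumptions,
not that the model fits any particular real population.

## Numerical choices and known limitations

- Tolerances: landmark closed forms to 1e-9 relative; velocity validated
  against central differences to 1e-6 relative; fit ties broken
  deterministically; monotonicity flagged when total velocity < −1e-6 on
  [0, 25] y.
- Degenerate inputs raise typed errors: no pubertal component (unalignable),
  rank-deficient transform, zero predicted weight, SD = 0 reference
  populations, out-of-range SDS queries.
- Problem sizes used in the validation suite — 200 subjects per sex for
  recovery, 500 for reference calibration, 240 with planted effects for
  subgroup directions — were chosen as the smallest sizes at which the
  Monte-Carlo error is clearly below the effect sizes being asserted.
- **Median-centred SDS carries a structural mean offset on skewed
  populations.** With the reference centred at the median (as printed growth
  references are) the population's mean SDS equals (mean − median)/SD per
  grid point, which reaches ≈ 0.07–0.14 where log-normal scale parameters
  and the nonlinear timing/tempo response skew the cross-sectional
  distribution — most visibly near and after the spurt. The package
  deliberately does no further skewness modelling (LMS/GAMLSS-style
  references exist for that); users comparing mean group SDS to zero should
  compare against a control group scored on the same reference, as the
  subgroup tooling does.
- Centile smoothing across age, BMI references, and mixed-effects joint
  fitting across subjects are out of scope.
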
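# qepsgrowth

Growth references are traditionally drawn against chronological age, even
though children enter puberty at very different ages: a healthy late maturer
can look underweight, and an early maturer overweight, simply because the
chart ignores biological maturation. `qepsgrowth` builds pediatric **weight
(and height) references aligned to each child's own onset of the pubertal
growth spurt**, so that weight development can be judged relative to
maturational stage. It is aimed at auxologists, growth-study statisticians
and developers of computerised growth-monitoring tools.

## The model

Individual growth is described by the additive, shape-invariant **QEPS
model**: a Quadratic (Q) and an Exponential (E) function arising before
birth carry *basic* growth; a logistic *pubertal* function (P) adds the
spurt; a delayed *stop* function (S) ends growth:

```
total(t) = c_Q·Q(t) + c_E·E(t) + c_P·P(t) − c_S·S(t)
basic(t) = c_Q·Q(t) + c_E·E(t)            − c_S·S(t)
```

Each basic function rises from 0 to 1, so six parameters are individual:
four scales plus pubertal timing `θ_P` (midpoint of P) and tempo `σ_P`.
Weight is modelled in **kg^0.5** — the scale on which the four components
combine additively (in kg the additivity is lost).

Because weight measurements are far noisier than height, weight is *not*
fitted with six free parameters. Instead the individual **height** fit is
transformed to a sqrt-weight curve with four population-level coefficients
(`c_X^weight = α_X · c_X^height`, timing and tempo shared), and a single
individual **weight–height factor** absorbs body constitution:

```
sqrt-weight(t) = (1 + WHF) · ŵ(t),   WHF = 0 normal, > 0 heavier, < 0 leaner
```

Landmarks: **AgeP5** (age at 5% of the pubertal gain `Pmax = c_P`) defines
spurt onset and the alignment origin `t′ = t − AgeP5`; **TPHV** (age at peak
height velocity) classifies pubertal timing. References report median and SD
per component (total / basic / puberty-specific) on a chronological grid
(4–20 y) and a puberty-aligned grid (−4…+10 y), and `SDS = (x − median)/SD`
in kg^0.5 space.

The study cohorts behind the published references are not public, so the
package ships a seeded synthetic-cohort generator with ground truth,
emulating per-sex longitudinal series from infancy to adult size with
individually varying pubertal timing and tempo, constitutional offsets,
irregular visits and measurement noise.

## Worked example

```python
from qepsgrowth import (CohortConfig, simulate_cohort, run_pipeline,
                        build_reference, sds, value_at_sds)

cohort, truth = simulate_cohort(CohortConfig(n_per_sex=100, seed=42))
result = run_pipeline(cohort)          # fit -> transform -> WHF
alphas = result.transforms["F"]
print(f"height->sqrt-weight transform (girls): "
      f"aQ={alphas.alpha_Q:.4f} aE={alphas.alpha_E:.4f} aP={alphas.alpha_P:.4f}")

curves = result.curves("weight", sex="F")
reference = build_reference(curves, axis="puberty_aligned", sex="F")
m = reference.median_at(0.0, "total")
print(f"median total weight at spurt onset (t'=0): {m**2:.1f} kg")
print(f"+2 SDS at t'=0: {value_at_sds(2.0, 0.0, reference):.1f} kg")
print(f"a 42 kg child two years after onset scores "
      f"{sds(42.0, 2.0, reference, 'total'):+.2f} SDS")
```

prints

```
height->sqrt-weight transform (girls): aQ=0.0419 aE=0.0448 aP=0.0817
median total weight at spurt onset (t'=0): 29.4 kg
+2 SDS at t'=0: 40.4 kg
a 42 kg child two years after onset scores +0.68 SDS
```

The α coefficients map cm of each height component to kg^0.5 of weight; the
median girl in this synthetic cohort weighs 29.4 kg when her spurt begins;
a 42 kg girl two years after *her own* onset is 0.68 SD above the aligned
median, regardless of the chronological age at which her puberty started.

The same pipeline is scriptable from the shell (`qepsgrowth simulate / fit /
transform / build-ref / align / classify / sds / assess`; `qepsgrowth config
show` prints every default).

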
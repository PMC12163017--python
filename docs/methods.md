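# Methods

## The model

A patient reports pain intensity on a bounded numerical pain scale (NPS,
0–10 throughout unless configured otherwise) not as a single number but
as an uncertainty interval `[lower, upper]`; a single number is the
degenerate interval with `lower == upper`. Within its interval, a
patient's pain intensity is modelled as a uniform random variable — the
minimal assumption when the patient asserts only a range. Pre- and
post-intervention intensities for the same patient are drawn
independently; no within-patient correlation structure is imposed
because none can be identified from interval data alone, and the
estimation procedure samples the two uniforms separately.

The per-patient treatment effect `post − pre` then follows the
convolution of two uniforms: a trapezoidal density on

```
[post.lower − pre.upper,  post.upper − pre.lower]
```

with linear ramps of width `min(w_pre, w_post)` at both ends and a flat
plateau of height `1 / max(w_pre, w_post)`. Equal widths give the
isosceles-triangle special case, a single zero width gives a rectangle,
and two zero widths give a deterministic point effect — the traditional
point-estimate analysis, which is handled outside the density machinery
(`PointMassError` directs callers there) to avoid dividing by a zero
width. The trapezoid is implemented exactly even though the
equal-width triangle is the visually familiar case: widths of, say, 1.6
and 1.4 genuinely produce a plateau of width 0.2, and treating it as a
triangle would misplace the mode region.

For the discrete 0–10 NRS the same construction runs on grid points:
each interval puts equal mass on the integers (or a configurable step)
it contains, and `discrete_difference_pmf` returns the exact pmf of the
difference by counting pairs. Interval bounds must lie on the grid; we
do not snap off-grid bounds because a misaligned bound is a data fault,
not a rounding choice.

## The estimator

`estimate_ate` propagates two sources of uncertainty into one empirical
sampling distribution of the average treatment effect (ATE):

1. **Sampling uncertainty** — resample the N patients with replacement
   (`b_outer` bootstrap cohorts, default 100).
2. **Measurement uncertainty** — for each bootstrap cohort and each of
   `b_inner` repetitions (default 100), draw one value from every
   patient's post-intervention uniform and one from the pre-intervention
   uniform, and form individual effects.
3. Average the individual effects into one ATE value per (outer, inner)
   pair.

All `b_outer × b_inner` values are pooled into a single distribution;
the point estimate is the pooled mean and the interval is the empirical
percentile interval at level `ci_level` (default 95%). Pooling, rather
than averaging inner replicates within each outer cohort, is the
simplest reading of "one empirical sampling distribution" and is the
default; it makes the interval reflect measurement uncertainty at full
strength. No bias correction (BCa) or normal approximation is applied.

Randomness follows a single seeded `numpy` Generator in a fixed order —
per outer cohort: resampling indices, then the post uniform block, then
the pre uniform block — so a seed determines the estimate bit-for-bit.
Seeds are mandatory in every stochastic entry point, including the CLI.

The estimator targets the realized cohort's *sample* ATE (the mean of
midpoint differences), not the generating population's effect; the two
differ by ordinary sampling error that shrinks with N. A single-patient
cohort is accepted (resampling is then trivial) but emits a warning
because sampling uncertainty is unestimable.

## The synthetic-cohort generator

`simulate_cohort` emulates an idealized before/after cohort: every
patient reports an interval of the same fixed width (3 NPS units by
default) centred on a latent midpoint. Defaults, in NPS units:

| parameter        | default | meaning                                        |
|------------------|--------:|------------------------------------------------|
| `n_patients`     |      50 | cohort size                                    |
| `true_ate`       |    −2.0 | population mean effect (negative = relief)     |
| `interval_width` |     3.0 | reported uncertainty width, equal for everyone |
| `pre_mean`       |     6.2 | mean pre-intervention midpoint                 |
| `pre_sd`         |     1.5 | SD of pre-intervention midpoints               |
| `effect_sd`      |     0.0 | between-patient SD of the individual effect    |

Pre-midpoints are Normal(`pre_mean`, `pre_sd`); each patient's post
midpoint is the pre midpoint plus a Normal(`true_ate`, `effect_sd`)
effect. The default `effect_sd = 0` (a constant individual effect) is
the simplest structure consistent with identical pre and post
dispersions; it also means pre and post midpoints are perfectly
correlated and the sample ATE is nearly deterministic, so generator
scatter across replicate cohorts mostly reflects boundary clipping.
`effect_sd` is exposed for heterogeneous-effect scenarios and is used in
tests that need between-patient variability. The midpoint distribution
is Normal by convention; nothing downstream depends on that choice and
it is isolated in one place.

Boundary handling: midpoints are clipped to
`[scale_min + width/2, scale_max − width/2]` so the full interval always
fits on the scale with its width intact. Truncating intervals instead
would silently vary the width across patients, which the fixed-width
design deliberately avoids. Clipping introduces a small bias in the
realized moments (≈0.04 units at the default settings, well inside the
calibration tolerances used in the tests).

`recenter_cohort` translates every post-interval by one constant so the
sample ATE hits an exact target (e.g. −1.8); only post-intervals move,
preserving the pre-intensity calibration, and the shift is rejected if
it would push any bound off the scale.

**What the generator does not emulate:** patient-varying interval
widths, within-patient pre/post dependence beyond the constant-effect
default, skewed or floor-inflated pain distributions, and missing or
half-open intervals. Passing tests therefore demonstrate correctness of
the machinery under idealized conditions, not robustness on real
clinical data.

## Sensitivity analyses

`sample_size_sweep` regenerates the cohort at each size in a grid
(default 5, 10, 20, 50, 100, 200, 500, 1000) with all other generator
parameters fixed and runs the estimator on each. Each sweep point gets
an independent sub-seed spawned from the master seed
(`numpy.random.SeedSequence`), so rows are independent yet the whole
sweep is reproducible.

`width_sweep` fixes one cohort and shrinks every interval about its
midpoint by a fraction (default 1.0 down to 0.0 in 0.1 steps; the grids
are a design choice spanning full width to the point-estimate limit).
Shrinking is exact: `width(result) = fraction × width(input)` with
midpoints untouched, so the sample ATE is invariant along the sweep and
only measurement uncertainty changes. At fraction 0 the data degenerate
to point estimates and the benchmark columns are filled.

**Wilcoxon benchmark.** The point-estimate benchmark is the paired
signed-rank procedure on within-patient midpoint differences, reported
as the Hodges–Lehmann pseudomedian (median of all N(N+1)/2 pairwise
Walsh averages) with its distribution-based confidence interval. The
interval uses the exact signed-rank null distribution (computed by a
small dynamic program) for N ≤ 25 and the standard normal approximation
with moments N(N+1)/4 and N(N+1)(2N+1)/24 beyond; index conventions
match R's `wilcox.test(conf.int = TRUE)`, against which the
implementation is cross-checked in the test suite. All differences
identical yields a degenerate interval with a warning. A "rank-sum"
test is unpaired by construction; the paired signed-rank reading is the
one that matches a before/after design, and we adopt it.

## Numerical choices

- Percentile CI endpoints use `numpy.quantile` with its default linear
  interpolation; with 10,000 pooled draws the interpolation choice is
  immaterial at the reported precision.
- The percentile interval must bracket the pooled mean for a unimodal
  pooled distribution; this is asserted (tolerance 1e−12) and violated
  only by pathological inputs, in which case the estimator fails loudly
  rather than returning an inconsistent summary.
- pdf/cdf are closed-form piecewise polynomials; normalization and the
  mean identity hold to quadrature tolerance 1e−9 and are tested against
  `scipy.stats.trapezoid` (an independent parameterization of the same
  law) and against Monte-Carlo sampling.
- CSV round-trips write floats at full `repr` precision, so
  write-then-read reproduces a cohort exactly. Reversed interval bounds
  are an error, never auto-swapped.
- Sub-seeds spawned for sweep points are reduced modulo 2³¹ so they stay
  valid plain-integer seeds everywhere.

## Problem sizes

The default analyses are deliberately modest: the proof-of-concept run
is N = 50 with a 100 × 100 bootstrap (10,000 pooled draws, well under a
second), the consistency check is N = 1000 with the same replicate
counts, and the property checks in the test suite use 10⁵-draw
Monte-Carlo comparisons per interval pair. These sizes make every
reported digit reproducible on a laptop while keeping Monte-Carlo error
an order of magnitude below the tolerances being asserted.

## Known limitations and non-reproducible published quantities

- The published 4-patient illustration reports an ATE of −0.6
  (95% CI −2.0 to 1.0), but only two of those four patients' intervals
  are available as printed numbers, so that figure is **not**
  desk-reproducible and is excluded from the acceptance checks here.
- The published N = 50 confidence-interval bounds (−2.0 to −1.6) are
  likewise excluded: they are narrower than independent pre/post
  sampling with pooled replicates produces, and the original pooling
  convention and pre/post correlation are not stated. Only the mean
  estimate is treated as a reproducible target; this package's
  percentile interval at N = 50 is wider (≈ −2.1 to −1.5).
- The estimator's theoretical properties (consistency rates, coverage
  under heterogeneous widths, behaviour under informative interval
  widths) are demonstrated empirically here, not derived.
- Only uniform (and discrete-uniform) within-interval distributions are
  implemented; alternative weightings (triangular, beta) would slot into
  the same interfaces but are out of scope.
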
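# Methods

## The model

`mesoproj` models a national surface of male mesothelioma deaths — counts
`Y[A, T]` by single year of age `A` (20–89) and calendar year `T`
(1968–2006 in the reference fit) — as independent Poisson observations
with mean

```
λ[A, T] = p(T) · ( c · u[A, T] + B[A, T] )

u[A, T] = P[A, T] · Σ_{l=0}^{A}  W(A − l) · D(T − l) · 2^(−l/H) · max(l − L, 0)^k
```

The sum runs over lag `l` (years before death).  Each past year contributes
the collective population dose `D(T − l)`, weighted by the exposure
potential `W` of the age the person then was, attenuated by fibre clearance
with half-life `H`, and amplified by the power `k` of time since exposure,
lagged by `L` years.  Exposure before birth contributes nothing (the sum is
truncated at `l = A`).  `P[A, T]` are person-years at risk, `B[A, T]` the
background (non-asbestos) cases and `p(T)` the recorded proportion
(diagnostic trend).  This is the classical power-of-time-since-exposure
description of mesothelioma risk applied at population level: individual
exposure histories are replaced by one collective yearly dose plus an
age profile.

### Components and parameters

| parameter | meaning | units | default / prior |
|---|---|---|---|
| `k` | exponent of time since exposure | – | U(0, 10) |
| `H` | fibre clearance half-life | years | fixed, 10⁶ (no clearance) |
| `L` | exposure→disease lag | years | fixed, 10 |
| `rate` | background cases | per million person-years | U(0, 20) |
| `W` (9 bands) | relative exposure potential by age | – | U(0, 10); ages 20–29 ≡ 1 |
| `peakyear` | maximum-exposure calendar year | year | discrete U(1950, 2000) |
| `D` knots (6 free) | exposure growth rates at `peakyear` + {−35, −25, −15, −5, +5, +15} | %/year | U(−100, 200) |
| `alpha` | diagnostic trend (optional, default off) | %/year | U(−7, 9) |

**Exposure curve.**  `D(T)` is built from growth rates pinned at knots
placed at offsets −65 … +15 around `peakyear` (the three earliest fixed at
0, 1000 and 100 000 %/year to force a negligible early level rising
steeply; the rate at `peakyear` is 0 by definition).  Rates for
intermediate years are linear interpolations; the curve steps
multiplicatively, `D(T+1) = D(T)·(1 + rate(T)/100)`, using the source
year's rate.  Exposure after `peakyear + 15` is assumption, not estimate:
a linear (in `D`) decline to 4% of peak in 2000, then linear through 2% of
peak in 2010 and 0.75% in 2050; these anchor ratios hold exactly after the
curve is normalised to `D(peakyear) = 1`.  The curve starts at
`peakyear − 80` (configurable); years before the first curve year
contribute zero exposure.  An alternative `"levelled"` scenario holds
exposure constant at its `peakyear + 15` level for sensitivity analyses.

**Background cases.**  `rate` per million person-years in total each year,
spread over ages proportional to `max(A − L, 0)^k` — the same power-law
shape as the asbestos term, read as risk rising with age.

**Diagnostic trend.**  Recording is treated as essentially complete (98%)
from 1997; earlier years miss more cases, growing backwards at `alpha`
percent per year.  The default model excludes the trend (`p ≡ 1`), which
fitted best in the reference analysis; when enabled, `p(T)` multiplies
both the asbestos and background components (both are recorded deaths).

**Scale.**  `D` is unit-free and normalised to 1 at the peak, so the
absolute scale of risk sits in the constant `c`.  During fitting `c` is
profiled out: it is chosen at every likelihood evaluation so that fitted
deaths over the fit window sum exactly to the observed total `M`, and the
same `c` carries into projection years.  The synthetic-data generator
instead takes an explicit `c` (normalising to its own output would be
circular); a calibration helper solves for the `c` giving a target
fit-window death total.

### Conventions and numerical choices

* **Lag indicator.**  Contributions with `l ≤ L` are zero
  (`max(l − L, 0)^k`).  This matches the background age shape `(A − L)^k`
  and avoids fractional powers of negative numbers at `l = L − 1`.
* Ages and years are integers on closed intervals; surfaces are indexed
  `[age, year]`.  The age of exposure is `A − l`, looked up in the nine
  piecewise-constant bands (0–4, 5–15, 16–19, 20–29, 30–39, 40–49, 50–59,
  60–64, 65+).
* Any parameter point where some `λ ≤ 0`, the curve is invalid, or the
  normalisation for `c` fails gets log-posterior −∞ (rejected by the
  sampler).
* The deviance uses the saturated-model convention
  `2 Σ [Y ln(Y/λ) − (Y − λ)]` with `0·ln 0 = 0`.

## Inference

Component-wise random-walk Metropolis–Hastings over the free parameters
with independent uniform priors: one parameter at a time in a fixed sweep
order, Gaussian steps for continuous parameters and symmetric integer
steps of size `max(1, round|N(0, s)|)` for `peakyear`.  Proposal scales
are tuned in pilot rounds toward a 20–45% acceptance band and frozen
before burn-in, so adaptation never touches retained draws.  The reference
run uses 20 000 burn-in sweeps and 35 000 retained draws (no thinning);
the bundled experiments use scaled-down chains (4 000 / 12 000) sized for
one CPU.  The RNG is numpy's PCG64 `Generator`; chains are
bit-reproducible given a seed.

### The peak-year label is not the peak-exposure year

The model contains a near-exact degeneracy: because the knots are anchored
*relative to* `peakyear`, a shifted label with compensating knot rates
describes almost the same calendar curve — the constraint
`rate(peakyear) = 0` does not force the curve maximum to the label year,
since interpolated rates may be negative before it.  Empirically the
profile likelihood over the label is flat to ~1 log unit across a decade,
while the argmax year of the realised curve is sharply identified.  Two
consequences for the implementation:

1. **Initialisation.**  A chain started at prior midpoints drifts into the
   nearest shifted basin and cannot escape (single-site moves cannot
   translate the curve).  `fit()` therefore initialises by default from a
   coarse profile-likelihood grid over `peakyear`, relabels the winner so
   the label coincides with its realised curve maximum (re-deriving knot
   rates from the curve's year-on-year growth at the new offsets), and
   re-optimises.  The prior-midpoint start remains available.
2. **Reporting.**  The "maximum exposure year" is summarised as the
   per-draw argmax of the realised exposure curve
   (`MesotheliomaResults.peak_exposure_summary`), not as the label
   parameter.  The label is still reported in `summary()`, where its
   near-zero acceptance rate makes its weak identification visible.

### Point fits

`fit_map()` maximises the log-posterior (equivalently the likelihood,
priors being flat) with L-BFGS-B in prior-width-normalised coordinates
(the knots span hundreds of %/year while `k` spans units; unnormalised
finite differences misbehave), profiling `peakyear` over a coarse integer
grid with warm starts and polishing with a ±1/±2 hill-climb.  It exists
for fast sensitivity sweeps — notably the lag profile — and for chain
initialisation; the sampler remains the inferential tool.

## Diagnostics

Model adequacy uses signed deviance residuals on an aggregated grid;
under a well-specified model they are approximately standard normal, so
~95% should lie in [−2, 2].  The default banding — 14 five-year age bands
by 9 calendar periods (one 7-year then eight 4-year periods over a
39-year window), 126 cells — is a reporting convention of this package,
chosen to give ~270 expected deaths per cell in the reference world; the
reference analysis reported 126 residuals without defining its banding,
and outputs label the convention as such.

## Projection

Each retained draw (evenly thinned to `n_draws`, default 500) is pushed
through the model on the full horizon with future person-years appended,
keeping the draw's own fit-window `c`.  Percentiles across draws of the
yearly λ-totals give the 90% credible interval of the expectation; a
Poisson realisation per draw adds sampling noise and gives the 90%
prediction interval (so the PI always contains the CI).  Peak summaries
take the per-draw argmax (ties to the earlier year); the peak-year
interval uses outward-rounded percentiles of the discrete draws.  The
20–89 series is rescaled to all ages by 1/0.99 by default (99% of male
mesothelioma deaths occur at ages 20–89).  Cumulative totals are computed
per draw, then summarised.

The lag sensitivity sweep refits the model at lags 0–15 with identical
priors and compares deviances and projected peaks.  The bundled
experiment pins `peakyear` at the generating value and uses the MAP
fitter — a deliberate desk-scale reduction; a full per-lag MH refit is
available via `fitter="mh"`.

## Synthetic data

`make_population` builds a smooth male person-years surface: totals
interpolate anchors (19.0 M in 1968 → 21.3 M in 2006 → 23.0 M in 2050,
the middle anchor matching the scale of the British male population aged
20–89), and the age structure is a gamma-shaped density over age whose
mode drifts from 38 to 46 (population ageing).  `simulate_deaths` runs the
model forward at a chosen truth and draws Poisson counts; the default
truth is the reference parameter point (k = 2.42, rate = 1.08, peak year
1963, the reference knot and age-weight estimates, H = 10⁶, L = 10, no
diagnostic trend) with `c` calibrated to 34 000 fit-window deaths.

The generator emulates the *statistical structure* the analysis assumes —
Poisson counts around a smooth λ-surface of the model's own form — and
deliberately not demographic detail: no migration shocks, no cohort
roughness, no misclassification, and the generating model is the fitted
model (no misspecification).  A green recovery test therefore establishes
internal consistency of simulate → fit → project, not correctness of the
model for real registry data.

## Known limitations

* The peak-year *label* is weakly identified (see above); its posterior
  within one chain understates that uncertainty because chains do not
  cross basins.  The realised peak-exposure year does not suffer from
  this.
* With ~34 000 fit-window deaths, the background-rate posterior is wide
  (90% CI roughly ±40% around 1 per million); single-realisation medians
  scatter accordingly.
* Exposure after `peakyear + 15` is assumption-driven; projections beyond
  the data window inherit that assumption, and the `"levelled"` scenario
  shows the sensitivity.
* The deviance-residual banding is a convention; conclusions about fit
  should not hinge on it.
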
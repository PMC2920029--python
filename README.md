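# mesoproj

Bayesian modelling and projection of asbestos-related mesothelioma
mortality from a national death register.

Mesothelioma is almost always caused by asbestos exposure and kills
decades after it — so today's death counts encode the population's
exposure history, and a fitted exposure history is what lets you project
the epidemic's peak and decline.  `mesoproj` implements a Poisson
regression for a death surface by single year of age (20–89) and calendar
year, in which the expected count is

```
λ[A,T] = p(T) · ( c · u[A,T] + B[A,T] ),
u[A,T] = P[A,T] · Σ_l  W(A−l) · D(T−l) · 2^(−l/H) · max(l−L, 0)^k
```

— a lagged power of time since exposure (`k`, lag `L`), a reconstructed
yearly collective dose `D(T)` parameterised by growth-rate knots around
the peak-exposure year, an age-specific exposure potential `W` (nine age
bands, ages 20–29 as baseline), fibre clearance with half-life `H`,
background (non-asbestos) cases `B` and a diagnostic-completeness trend
`p`.  The model is fitted by component-wise random-walk
Metropolis–Hastings under uniform priors, giving credible intervals for
parameters and prediction intervals for future deaths.  Because national
register data are not redistributable, the package ships a synthetic-data
generator with the same statistical structure, so the whole
simulate → fit → diagnose → project pipeline runs self-contained.

It is intended for epidemiologists and biostatisticians working on
asbestos-related disease burden, and for anyone who wants a tested,
reusable implementation of this class of latency/exposure-reconstruction
models.

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.

## Worked example

Simulate a register-like world at the reference parameter point
(k = 2.42, background rate 1.08 per million, peak exposure 1963, ~34 000
deaths over 1968–2006), refit it blind, and project to 2050:

```python
from mesoproj.experiments import run_recovery

study = run_recovery(seed=1)          # simulate + MH refit (~2 min)
print(study.results.summary().loc[["k", "rate", "W:30-39"]].round(3))
print(study.results.peak_exposure_summary())

future = study.population.year_slice(2007, 2050)
proj = study.results.project(future, seed=1)
print(proj)
print(proj.table.set_index("year").loc[[2010, 2016, 2030, 2050]].round(0))
```

prints

```
           median    ci5   ci95  acceptance  mode
parameter
k           2.473  2.381  2.569       0.209   NaN
rate        1.071  0.721  1.443       0.399   NaN
W:30-39     1.648  1.514  1.790       0.258   NaN
{'mode': 1963, 'median': 1963, 'ci': (1963, 1963)}
peak 2150 deaths (90% PI 2072-2259) in 2013 (90% CI 2012-2013)
      median   ci_lo   ci_hi   pi_lo   pi_hi
year
2010  2134.0  2093.0  2172.0  2045.0  2218.0
2016  2114.0  2046.0  2178.0  2014.0  2223.0
2030  1296.0  1196.0  1398.0  1181.0  1416.0
2050   334.0   288.0   384.0   277.0   387.0
```

Reading this: the blind refit recovers the generating exponent
(k: median 2.47, 90% CI 2.38–2.57 around the true 2.42), the background
rate (1.07 vs 1.08) and the 30–39 exposure weight (1.65, 90% CI
1.51–1.79 against a true 1.79); the realised exposure curve peaks in 1963
in every retained draw.  In this synthetic world the epidemic peaks in 2013 at about 2 150
male deaths per year (all-ages rescaling 1/0.99 applied) and declines
steeply thereafter; the wider `pi_*` columns are 90% prediction intervals
for realised counts, the `ci_*` columns 90% credible intervals for the
expectation.

The same pipeline is scriptable from the shell:

```sh
mesoproj simulate --config config.json
mesoproj fit      --config config.json
mesoproj diagnose --config config.json
mesoproj project  --config config.json --scenario decline
mesoproj sensitivity --config config.json --lag 0 --lag 10 --lag 15
```

Each stage writes CSV artifacts plus a JSON manifest (seed, input
checksums, version) and is bit-reproducible from its manifest.

## Acceptance script

`scripts/acceptance.py` recomputes the headline recovery quantities from
scratch — it simulates the reference world at the seed you give, refits
it blind with the MH sampler, and writes the recovered posterior
summaries (the exponent of time, the background rate, the peak
population-exposure year, and the 30–39 exposure weight) as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is a few minutes on one CPU; the chain is a documented
scaled-down version (4 000 burn-in, 12 000 retained) of the reference
20 000 / 35 000 run.
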
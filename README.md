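# deersurvey

Three independent estimators of white-tailed deer (*Odocoileus
virginianus*) population density over a moderately large (~10 km²)
protected area, implemented as one tested pipeline:

1. **Camera-trap mark–resight ratios.** Antlered males are individually
   identifiable, so the "population factor" *f* = unique males / male
   photographic occurrences converts female and fawn occurrence tallies to
   unique-individual scales:

   *N̂* = *E* · (*U*ₘ + *f·O*_f + *f·O*_y),  *D̂* = *N̂* / *A*,

   with extrapolation factor *E* (default 1.10) correcting for animals
   never photographed. The 95% CI resamples camera sites with replacement.

2. **Binomial–Poisson N-mixture model** for repeated point counts with
   imperfect detection:

   *N*ᵢ ~ Poisson(λᵢ), log λᵢ = **x**ᵢ′**β**;  *C*ᵢⱼ | *N*ᵢ ~
   Binomial(*N*ᵢ, *p*ᵢ), logit *p*ᵢ = **x**ᵢ′**α**,

   where *C*ᵢⱼ is the daily maximum count at site *i* on day *j* and the
   covariates are site elevation, slope, north–south aspect (cos of the
   compass aspect) and distance to the area edge. The marginal likelihood
   sums the latent abundance to a truncation bound *K*; candidate covariate
   structures (up to two predictors per component, 101 models for four
   predictors) are ranked by AIC; density is the sum of empirical Bayes
   posterior-mean site abundances (BUPs) divided by the camera-sampled
   area, with a Monte Carlo credible interval.

3. **Drone strip-transect counts.** Thermal overflights of parallel strip
   transects with assumed perfect within-strip detection: transect density
   = count / (length × swath), flight density = mean over transects, survey
   density = mean over flights with a flight-level percentile bootstrap CI
   and a one-way ANOVA across flights.

A synthetic-data module generates landscapes, camera-count matrices,
marked-male photo streams and strip-transect surveys with known ground
truth, so every estimator is validated by parameter recovery without any
field data. The package is aimed at quantitative wildlife ecologists and
managers comparing survey designs for unfenced ungulate populations.

## Worked example

Generate a fully synthetic survey mirroring the default study design
(22 cameras ~636 m apart on 10.24 km², a 90-day winter season, 5 drone
flights over 12 transects) and analyse it with all three estimators:

```sh
$ deersurvey simulate --preset pmsp --seed 42 --out simout
wrote synthetic survey (true density 28.0 deer/km^2) to simout

$ deersurvey mark-resight --tallies simout/tallies.csv --extrapolation 1.0 --nboot 2000 --seed 1
density: 26.4 deer/km^2 (95% CI 22.9-29.9); population factor 0.127

$ deersurvey drone --transects simout/transects.csv --nboot 2000 --seed 1
density: 29.8 deer/km^2 (95% CI 26.7-33.2)
ANOVA across flights: F(4,55) = 0.93, p = 0.45
```

The simulated truth is 28.0 deer/km²; the mark–resight ratio (26.4) and
the drone survey (29.8) both bracket it. The population factor 0.127 means
each identifiable male was photographed about 8 times, and the
non-significant ANOVA (p = 0.45) says the five flights are mutually
consistent. `deersurvey fit-nmix` runs the N-mixture candidate set on the
same counts; note that with daily detection probabilities around 0.04 its
abundance–detection likelihood ridge makes single-survey densities much
noisier than the other two methods (see `docs/methods.md`). The same
analyses are available as library functions (`mark_resight_estimate`,
`fit_nmix`, `drone_survey_estimate`, …) and as a single configured run via
`run_pipeline`, which also applies the mutual-containment rule: two
estimates are *statistically indistinct* when each point estimate lies
inside the other's 95% interval.

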
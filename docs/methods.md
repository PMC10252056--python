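# Methods

## Models and estimators

### Mark–resight ratio estimator

Tallies are aggregated over sites before the ratio is formed: the
population factor *f* = Σ unique males / Σ male occurrences, unique
females = *f* × Σ female occurrences, unique fawns = *f* × Σ fawn
occurrences, population = extrapolation × (unique males + unique females +
unique fawns), density = population / area. The estimator assumes (i)
equal sighting rates across demographic classes, (ii) a closed population
over the tally window, and (iii) that a male resighted at several sites is
rare under the camera spacing. Unique males are deduplicated **within**
site and summed across sites by default, which keeps every site's tally
self-contained and therefore compatible with the site-resampling
bootstrap; a `dedupe="global"` mode (each identity counted once park-wide)
exists for sensitivity analysis. Bootstrap replicates resample the *n*
sites with replacement; a replicate with zero male occurrences leaves the
factor undefined and is redrawn (the count of redraws is logged). The
interval is the plain 2.5/97.5 percentile of replicate densities.

Key parameters: extrapolation factor (default 1.10, the empirical
correction for a three-month baited-survey window; use 1.0 when the
simulation truth contains no unseen animals), area (default 10.24 km²),
`n_boot` (default 10,000).

### Binomial–Poisson N-mixture model

Latent site abundance N_i ~ Poisson(λ_i) with log λ_i = x_i′β; counts
C_ij | N_i ~ Binomial(N_i, p_i). The printed form of the detection link in
the source literature is a log link, but a log link does not keep p in
[0, 1]; the default here is the logistic link (the convention of the
standard `pcount`-style implementations), with `link="log"` available (the
fit then rejects parameter regions implying p ≥ 1). Covariates are z-score
standardized (n−1 denominator) before fitting and coefficients are
reported on the standardized scale; the scaling is stored on the fit for
back-transformation.

The site marginal likelihood sums Poisson(N; λ_i) Π_j Binomial(c_ij; N,
p_i) over N from max_j(c_ij) to a truncation bound K, entirely in log
space. Because p is constant within a site, the binomial product collapses
to sufficient statistics and one likelihood evaluation costs O(K) per site
(precomputed Σ_j lgamma(N − c_ij + 1) tables); the general per-occasion-p
form is kept for the public `site_marginal_loglik`. K defaults to the
maximum observed count + 100; a K-stability property test verifies the
log-likelihood is insensitive (<1e−8) to raising K further.

Fitting is quasi-Newton (L-BFGS-B, finite-difference gradients, ftol
1e−10) from a deterministic start: β₀ = log(mean site maximum + 0.5),
α₀ = 0 on the logit scale (log 0.5 under the log link), all slopes 0.
Standard errors come from inverting a central-finite-difference observed
information matrix; z-scores and two-sided normal p-values follow. A
singular information matrix yields NaN SEs and `ses_ok=False` rather than
an exception. Degenerate data (all-zero counts, or any coefficient pushed
past ±25 on the standardized scale) set `converged=False`.

Candidate sets take every subset of one or two predictors in each
component (10 × 10 = 100 models for four predictors) plus the null model.
AIC = 2k − 2 log L ranks converged fits; ties prefer fewer coefficients,
then lexicographic model labels.

Empirical Bayes site-abundance posteriors are computed by **exact
enumeration** over 0…K — the support is finite, so simulating the
posterior would only add sampling noise; the distribution is identical.
The best unbiased predictor (BUP) is the posterior mean; the 95% credible
interval is the central [2.5%, 97.5%] quantile pair on the integer
support. The aggregate density divides the summed BUPs by the
camera-sampled area; its interval is Monte Carlo (default 10,000 draws of
independent site abundances from the posterior pmfs), since the sum has no
convenient closed form.

### Drone strip transects

Transect density = count / (length × swath); flight density = unweighted
mean of its transect densities, following the survey description, even
though transects differ in length — an area-weighted `mode="pooled"`
estimator (flight total count / flight strip area) is provided and is the
one invariant to splitting transects. Survey density = mean of flight
densities; the CI is a percentile bootstrap over the (typically five)
flight densities. Detection within the strip is assumed perfect. The
across-flight test is one-way ANOVA on per-transect densities grouped by
flight — with a single factor the type II sum-of-squares decomposition
equals the ordinary between/within decomposition — with the p-value from
the upper tail of F(df_between, df_within).

### Comparison rule

Two estimates are "statistically indistinct" iff each point estimate lies
inside the other's 95% interval (mutual containment). This is stronger
than interval overlap: two wide overlapping intervals whose means sit
outside each other still count as distinct. The rule is symmetric, and
`run_pipeline` applies it to every pair of estimates it produces. Report
timestamps are isolated in a single `generated_at` field so reruns under
fixed seeds are otherwise byte-identical.

## Ingest conventions

Daily maximum counts: the largest total deer count in any single
photograph at a site within a civil day (midnight split, local time),
guarding against repeat-counting within a day. Days with no photographs at
an operating camera are observed zeros, since monitoring was continuous;
an optional per-site activity table marks outage days as missing instead,
and missing occasions are simply dropped from that site's likelihood
term. Seasons are three-month bins (summer Jun–Aug, autumn Sep–Nov, winter
Dec–Feb tagged by the December year, spring Mar–May).

Terrain covariates come from a single-band elevation grid (plain-text
ESRI-ASCII layout): slope and downslope aspect by Horn's 3×3
finite-difference stencil, with border cells handled by edge replication
(one-sided differences) and flat cells assigned slope 0 and aspect_ns 0
(no north–south component); aspect_ns = cos(aspect), so +1 faces north and
−1 south; distance to edge is the Euclidean distance to the boundary
polygon ring.

## Synthetic data

The generator reproduces the statistical structure the estimators assume,
with the study's design constants as defaults: a rectangular 10.24 km²
region, 22 camera sites on a regular grid at 636 m spacing (±15 m jitter),
smoothed-Gaussian-noise elevation (length scale 300 m, relief ~120 m, 30 m
cells) in place of a real DEM — only the covariate structure matters to
the estimators — 90 daily occasions per season, and 12 east–west strip
transects 300 m apart with a 100 m swath summing to 13.75 km (1.375 km²,
~13.4% of the area), the four northernmost shortened as in the original
aborted-transect layout.

Counts are drawn exactly from the N-mixture data model (N_i once per
season, binomial thinning per day) with winter-season generating
coefficients β₀ = 2.51, β_aspect = −0.26, β_elev = 0.23; α₀ = −3.19,
α_slope = −0.29 (logit). The mark–resight simulator gives each individual
one home site and Poisson sightings at 0.08 per day over 90 days — chosen
to match the observed winter photo volume (~1700 photographs for a
population of roughly 280 implies 6–7 sightings per individual) — with an
optional Gamma rate heterogeneity (shape 1/heterogeneity), which is known
to bias the ratio estimator and is exercised directionally, not asserted
numerically. The demographic split defaults to 1 male : 2 females : 0.6
fawns; recovery checks are invariant to the split under homogeneous rates.
Drone flights redraw an independent uniform Poisson point process per
flight (animals redistribute between flights) and count points inside each
strip. The `pmsp_scenario` preset ties all three surveys to one shared
true density (implied by the abundance coefficients over the generated
landscape, ~28 deer/km²).

What the generator does **not** emulate: animal movement and home-range
overlap between camera sites (individuals are pinned to one site),
day-to-day behavioural correlation, group (herd) structure in photographs,
distance-dependent detection in the drone strips, and real terrain.
Passing recovery tests therefore demonstrate correctness of the estimators
*under their own assumptions*, not robustness to the field violations of
those assumptions.

## Numerical choices

- All likelihood and posterior arithmetic in log space (`logsumexp`,
  `xlogy`, `xlog1py`); posteriors that underflow entirely raise with a
  suggestion to increase K.
- Percentile intervals use `numpy.percentile` (linear interpolation);
  integer-support credible intervals use the smallest central quantile
  pair via the posterior CDF.
- Seeds: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); composite runs derive sub-seeds with
  `SeedSequence.spawn`, keeping all seeds below 2³¹.
- Simulation-study sizes (100 surveys for coefficient recovery, 50 for
  density recovery, 500/200 for mark–resight, 200 for drone) balance Monte
  Carlo error on coverage proportions (±2–3 points at n = 200) against a
  test suite that runs in about a minute.

## Known limitations

- **Low-detection weak identifiability.** At the winter operating point
  (daily p ≈ 0.04) the N-mixture likelihood is nearly flat along the λ–p
  ridge: counts are approximately Poisson(λp), and only the weak
  within-site correlation across occasions separates abundance from
  detection. With 22 sites the intercept MLEs are strongly skewed (the
  abundance and detection intercepts err in opposite directions), Wald
  coverage stays near nominal only because the SEs are correspondingly
  large, and the empirical-Bayes density inherits an upward mean bias of
  tens of percent. Slope coefficients — the ecological effects — are
  recovered essentially unbiased. The acceptance script reports all of
  these quantities; the recovery tests document where the model's own
  small-sample behaviour, not the implementation, violates idealised
  expectations. In an information-rich regime (p = 0.5, 100 sites) the
  same code recovers intercepts and densities without measurable bias.
- **Conservative site bootstrap.** When the sighting rate makes the
  camera survey a near-census (any rate consistent with the observed photo
  volume does), the mark–resight point estimate has almost no sampling
  error while the site-resampling interval reflects between-site
  allocation heterogeneity, so its empirical coverage approaches 100%.
- **Five-flight percentile bootstrap.** A percentile bootstrap of a mean
  of five values cannot reach nominal 95% coverage (~84% even for ideal
  normal data); the drone interval should be read accordingly.
- No open-population, negative-binomial or zero-inflated N-mixture
  variants; no spatially explicit mark–resight; no distance-sampling
  detection function for the aerial strips.
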
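# Methods

`footsel` implements a two-stage analysis of mammal space use against a
fine-scale human-footprint index in protected areas, comparing an "open"
year with ordinary visitation (2019) against a "closure" year (2020), and a
synthetic data generator that makes every stage testable with known truth.

## Human-footprint index

Five infrastructure classes contribute: roads, trails, car parks, buildings
and campgrounds.  For class *c* with weight *w_c* ∈ [0, 1] and decay scale
*s_c*, the influence at a cell at distance *d_c* from the nearest feature is
*w_c* · exp(−*d_c*/*s_c*).  Per-class influences are combined with the
complement-of-product rule

    footprint = 1 − Π_c (1 − w_c e^{−d_c / s_c}),

which is bounded in [0, 1] with no post-hoc rescaling, symmetric in class
order, monotone in every influence, and saturates at 1.0 on a feature of a
weight-1 class.  A renormalised weighted sum is available as an alternative
aggregation for sensitivity analyses.  Default class parameters (weight,
decay scale in m): building (1.0, 500), campground (0.9, 500), parking
(0.8, 500), road (0.8, 750), trail (0.4, 250).  These defaults rank
permanent, high-occupancy structures above trails; they are deliberate,
configurable stand-ins — the index construction, not any particular weight
set, is the method.  Distances are measured from 30 m cell centres; cells
whose centre lies on a feature get distance 0.

Land-cover distances use the exponential decay y = e^{−x/750} (in metres),
which falls to 5% of its initial value at 2.25 km.

## Track preparation

Raw GPS fixes are screened for errors (exact-duplicate timestamps; fixes
implying straight-line speed above a configurable threshold, default
10 m/s, from the previous retained fix), thinned to a 4 h fix interval
(tracks whose median interval already exceeds the target are left on their
original schedule; a ±30 min tolerance with ties broken toward the earlier
fix makes the thinning deterministic and idempotent), and clipped to the
closure window and its month-day-matched counterpart in the open year.
Individual-years are then dropped if they have fewer than 30 fixes, more
than half their fixes outside the park, or a home-range mean footprint
below 0.02.  The last default needs justification: the filter exists
because a coefficient on an essentially constant covariate is
unidentifiable, and a home range whose mean footprint is ~0.01 in a [0, 1]
index varies too little for the selection coefficient to mean anything.
A threshold so low that it never fires would defeat the filter's purpose.
All three thresholds are configuration.

## Used/available design

The home range of each individual-year is the 95% isopleth of a bivariate
Gaussian kernel utilization distribution (KUD): per-axis reference
bandwidths h = sd · n^{−1/6}, density evaluated on a fixed 7.5 m grid (4×
the raster resolution), isopleth taken as the smallest-density contour
holding 95% of mass.  Available points are drawn uniformly within the
isopleth at a 1:50 used:available ratio (rejection sampling, seeded).

Covariates at every point: footprint (raw, so its coefficient stays on the
interpretable [0, 1] scale), elevation and slope (centred and scaled to
mean 0, sd 1 within each population, pooling used + available rows across
both years so cross-year contrasts are on one scale), and five decayed
land-cover distances (decay then centre/scale, same pooling).  A Pearson
correlation screen over all 28 covariate pairs per population (available
rows only, since the screen characterises the habitat domain) reports
|r| > 0.7 pairs; flagged pairs are reported, never auto-dropped.

## Hierarchical resource selection function

One model per population.  For individual-year *j* and point *i*:

    used_i ~ Bernoulli(p_i)
    logit(p_i) = β_intercept[j] + β_footprint[j]·footprint_i
               + β_elevation[j]·elevation_i + β_slope[j]·slope_i
               + Σ_c I_c[j] · β_c[j] · cover_{c,i}

with presence indicators I_c[j] ∈ {0, 1} masking land-cover classes absent
from the home range.  Individual coefficients come from population
hyperdistributions: β_jk ~ Normal(μ_k, τ_k) for the intercept, footprint,
elevation and slope; the five land-cover coefficients jointly from a
multivariate normal with precision matrix Λ.  Hyperpriors: μ_k ~
Normal(0, precision 0.01); intercept sd ~ Uniform(0, 100) transformed to
precision; τ ~ Uniform(0, 25) for footprint/elevation/slope (a prior on
the precision itself, honoured literally — it bounds the
between-individual sd below at 0.2); Λ ~ Wishart(I₅, 6 df).  With an
identity scale matrix the scale-vs-inverse-scale convention is numerically
moot; the implementation pins "identity = scale matrix of the precision
prior" for non-identity configurations.

Derived quantities: per-year population means of the footprint coefficient
(draw-wise average over that year's individuals), the draw-wise 2020−2019
difference, and avoid/select/neutral calls from whether the equal-tailed
95% credible interval excludes zero.  The hyper-mean μ_footprint is the
population-level estimand used in recovery studies (its posterior carries
the between-individual variance; the draw-wise average of realised
individuals deliberately does not).

### Sampler

The posterior is sampled with Metropolis-within-Gibbs, written for this
model (any sampler with the same stationary distribution is acceptable;
the model, priors and chain settings are the contract):

* per individual, a blocked random-walk Metropolis update of the 9-vector
  β_j, proposal covariance from a Laplace approximation at a ridge-penalised
  MLE with its information eigenvalues floored at 1 (barely identified
  directions fall back to a hyperprior-scale proposal while well-identified
  correlated ridges keep their exact geometry), a global per-individual
  scale adapted to 23% acceptance during burn-in only;
* per coefficient, a translation update that shifts μ_k and every β_jk by
  the same amount (the β|μ prior cancels; only the likelihoods and the μ
  prior enter).  This interweaving-style move decorrelates the population
  level from the individual effects, the dominant slow direction of the
  centred parameterisation;
* conjugate Gibbs draws for the hyper-means (normal), scalar precisions
  (truncated gamma via inverse-CDF; the J = 1 intercept case degenerates to
  a non-gamma density and falls back to a Metropolis step on log τ) and the
  land-cover precision matrix (Wishart).

Chains are initialised over-dispersed around empirically shrunk Laplace
fits — each coordinate pulled toward the information-weighted pooled mean
of the per-individual MLEs — because raw MLEs of unidentified coordinates
can sit at ±50 and leave finite burn-ins stranded.  Initialisation does
not alter the target distribution.

Published chain settings (3 chains × 30 000 iterations, 3000 burn-in,
thinning 3) are available via `published_mcmc_config()`; the package default is
a sized-down 3 × 3000 (burn-in 1200, thinning 3) used throughout the tests.
Convergence is judged by per-parameter split-chain Gelman–Rubin R̂ with the
pass rule max R̂ ≤ 1.1; a non-converged fit is flagged with a warning, not
silently returned.

## Second stage: change model and functional response

First-stage footprint coefficients enter second-stage regressions as
observations with known measurement precision τ_j = 1/sd_j² (no residual
variance term beyond measurement error — the likelihood is exactly the
stated one; an optional additive residual sd, default off, exists because
the literal model can be underdispersed).  With Normal(0, precision 0.01)
priors the posterior is Gaussian in closed form; draws from the analytic
posterior provide interval summaries, and the flat-prior limit equals
weighted least squares, which the tests exploit as an oracle.

* Change model: for animals tracked in both years, Δβ_footprint[j]
  (preferably the draw-wise 2020−2019 difference; quadrature-combined sds
  are the fallback when only per-year summaries survive) regressed on 2019
  exposure with per-population intercepts and a common slope.
* Functional response: all individual-year coefficients regressed on
  exposure (mean footprint over the available points of that
  individual-year's home range — computed once from the used/available
  table and shared by both models).  Global structure: population-year
  intercepts, one slope per year.  Guild structure: slopes per guild-year
  (the lone small carnivore is excluded).  Species structure: species-year
  intercepts and slopes.  Slope groups with fewer than two observations or
  no within-group exposure variation are flagged unidentifiable.

Exposure in each year uses that year's home range (individual-year KUDs
exist, so re-estimation per year is the natural reading).

## Synthetic data generator

The generator emulates the study's withheld telemetry.  A landscape
(default 6 × 6 km at 30 m) carries smoothed-noise elevation (and derived
slope), five land-cover classes obtained by thresholding an autocorrelated
field at fixed area shares (forest 0.40, herbaceous 0.25, scrub 0.20,
barren 0.10, water 0.05), and infrastructure concentrated along a road
corridor with a small visitor node, so the footprint index spans a genuine
gradient (near 1 at the node, near 0 a few kilometres away).

Each individual receives a disc home range (default radius 600 m) placed
uniformly; its exposure is the mean footprint over disc cells.  Per year,
its footprint coefficient is drawn Normal(fr_intercept[year] +
fr_slope[year] · exposure, sd) — the generative inverse of the functional
response — and the other coefficients from their population distributions.
Used locations are exact categorical draws over disc cells with probability
∝ exp(linear predictor), jittered uniformly within the 30 m cell;
timestamps are evenly spaced at the 4 h default fix interval inside a
58-day closure window (28 March – 24 May), matched across years.  Default
truth values: footprint population means −1.88 (open year) and −1.75
(closure year) — the published cross-population means — with zero exposure
slope; an alternative truth with slopes −1 (open) and +4 (closure)
reproduces the qualitative open-negative/closure-positive pattern for
functional-response studies.  Between-individual sds default to 0.5
(footprint), 1.0 (intercept) and 0.3 (others), inside the support implied
by the τ ~ U(0, 25) prior.

The generator does **not** emulate: movement autocorrelation (fixes are
conditionally independent draws, so the 4 h resampler sees no serial
structure to remove), behavioural states, migration or hibernation events,
multi-park geometry, or GPS measurement error.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to real-data pathologies.

### Availability misspecification: a deliberate design choice

A used/available RSF estimates selection *relative to the availability
sample*.  The generative truth here is defined relative to uniform
availability on the true disc.  If available points are instead drawn
uniformly from an *estimated* 95% KUD polygon, the polygon's error enters
the coefficients directly: the KUD of fixes from a uniform disc includes a
spill ring (roughly 1.6 bandwidths wide, 20–30% of the polygon area at
n ≈ 150) that holds available points but essentially no used points, and in
development gradients this biased per-individual footprint coefficients by
several units, with sign flips for high-exposure individuals.  This is not
a sampler defect — it is what availability misspecification does to an RSF,
and in field studies the home-range polygon *is* the definition of
availability rather than an estimate of some other true region.

The pipeline therefore exposes two availability modes: `"kud"` (the field
protocol, exercised by the integration tests) and `"truth"` (the
generator's own disc, matching the estimand).  Parameter-recovery studies
use `"truth"`: they test whether the hierarchical model recovers the
generating coefficients when availability is correctly specified, which is
the property the model can honestly claim.

## Problem sizes and numerical choices

Test and acceptance runs use sized-down configurations chosen as the
smallest designs at which the checks are informative: convergence on 10
individuals × 150 used points (1:20) with 3 × 3000 iterations; recovery
coverage over 10 replicates of 10 × 120 (1:15) with 3 × 2400 iterations;
single-individual MLE agreement on 250 used points (1:20) with 3 × 6000.
Tolerances: recovery demands ≥ 8/10 CI coverage (binomial slack at 10
replicates); MLE agreement within 0.05 per coefficient (Monte-Carlo error
plus posterior-mean-vs-mode skew at near-flat priors); the
measurement-error point estimate matches weighted least squares to 1e-6.
Draw bookkeeping is exact: (iterations − burn-in) must divide by the
thinning rate, and reported draw counts equal chains × that quotient.

Known limitations: the KUD availability path carries the bias analysed
above, so population estimates from the full field protocol on synthetic
discs are attenuated relative to generative truth; the Uniform(0, 25)
precision prior cannot express between-individual sds below 0.2; exposure
and coefficient uncertainty enter the second stage as known precisions,
ignoring error in exposure itself.  When second-stage models are fed
posterior means from the hierarchical first stage, shrinkage of data-poor
individuals toward the population mean flattens the coefficient-exposure
relationship and attenuates functional-response slopes — markedly so in
designs dominated by low-exposure individuals, whose footprint
coefficients are barely identified.  Functional-response recovery is
therefore demonstrated on coefficient observations with known measurement
sds (the model's own error structure); end-to-end functional-response
estimates from small simulated populations should be read as conservative.
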
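# Methods

## Model

Route-level counts of breeding upland game birds are modeled
hierarchically.  Latent abundance on route *i* in year *t* is

    N[i,t] ~ NegBin(s[i,t], r),   s[i,t] = r / (r + μ[i,t]),

the parameterization in which μ = r(1 − s)/s is the mean and
μ + μ²/r the variance, so r controls extra-Poisson dispersion.  The
log mean is a piecewise-linear (continuous hinge) regression

    log μ[i,t] = β0 + β·X[i,t] + (β5 + δ·1[x[i,t] − φ ≥ 0])·(x[i,t] − φ) + ε[i,t]

with X the four standardized weather covariates (summer drought index,
winter precipitation, summer maximum temperature, winter minimum
temperature), x the standardized landscape covariate carrying the
change point (percent grassland or grassland edge density), φ the
threshold, β5 the pre-threshold slope, δ the slope change after it,
and ε[i,t] ~ Normal(0, σ) an exchangeable route-year intercept.  The
indicator is 1 exactly when x − φ ≥ 0 (ties fall on the post-threshold
side); the hinge multiplies (x − φ) on both sides of the threshold, so
the predictor is continuous in x at φ for any δ.

Two observation layers share this process.  In the lek design each of
J ≥ 2 within-season visits is a binomial thinning
y[i,j,t] ~ Binomial(N[i,t], p), which identifies a single global
detection probability p under the usual closure assumptions.  Real
surveys surely have visit- and site-varying detection; with no
covariates to structure it, the fitted p is a season-level average, and
the model is honest only about that average.  In the direct
(single-visit) design the count itself is the negative binomial draw;
abundance there is an index, not a detection-corrected estimate.

ε is interpreted as one draw per route × year cell.  A reading with
separate additive route and year intercepts is defensible; the single
cell-level term is the default because the model's subscripts attach
the intercept to the route-year, and the spec of the generator mirrors
that choice.

## Covariates

Weather windows are fixed: the drought covariate is the mean June-August
Palmer Drought Severity Index of the year before the survey; summer
temperature is the lagged June-August maximum of monthly TMAX; winter
temperature is the December-February minimum of monthly TMIN and winter
precipitation the December-February mean of monthly totals, both
spanning the calendar-year boundary (December belongs to the previous
year).  Any missing month makes the covariate explicitly missing;
affected route-years are flagged and excluded from the likelihood, never
imputed.

Land-cover values are constant within a Conservation Reserve Program
contract period and paired to survey years through the period table.
Covariates are z-scored with the sample (n−1) standard deviation, the
statistics computed once over all route-years entering a model and
shared by the simulator, the fitter and the back-transformer.  This
matters because the threshold prior is Uniform(l, u) with l, u the
standardized covariate's observed extremes: simulator and fitter must
agree on what "standardized" means for φ to be comparable.

## Landscape metrics

On a classified 30-m grid, percent grassland is 100 × grassland cells /
valid cells within the buffer; nodata cells leave the denominator.
Edge density sums the lengths of rook-adjacent cell faces between
grassland and valid non-grassland cells (both inside the buffer; faces
against nodata or across the buffer boundary are not edges) and divides
by the grassland area in hectares, giving m/ha.  That grassland-area
denominator is the package default; the conventional class edge-density
normalization by total landscape area is available via
`denominator="landscape"`, because the two definitions genuinely
disagree and users may need either.  A landscape with no grassland has
undefined edge density (NaN), not zero.

Buffers include cells whose center lies within the radius of the route
polyline (Euclidean distance, shapely); fractional-cell weighting is
out of scope.  Coordinates are plain projected meters — no CRS
handling.  Raster I/O supports the ESRI ASCII grid format.

## Priors and their readings

β0, β1-β4, β5 ~ Normal(0, 10); δ ~ Normal(0, 10); r ~ Gamma(1, 1);
φ ~ Uniform(l, u); p ~ Uniform(0, 1).  The Normal scale parameter is
read as a standard deviation by default — the only reading that is
weakly informative for a log-scale regression — but
`scale_interpretation` accepts `variance` or `precision` so either
alternative reading is runnable.  The random-intercept scale uses
σ ~ HalfNormal(15) by default; `sigma_fixed` instead pins σ at a
constant (the literal fixed-scale reading of ε ~ N(0, 15) is
`sigma_fixed=15`).

## Sampling

The sampler is adaptive Metropolis-within-Gibbs on the marginalized
likelihood.  Scalar parameters (β's, δ, φ, log r, logit p, log σ) take
Gaussian random-walk proposals; step sizes adapt toward 0.44 acceptance
during burn-in only, so the post-burn-in kernel is fixed and the chain
valid.  The route-year intercepts are proposed jointly and
accepted/rejected independently per cell, which is exact because each
ε touches exactly one likelihood term.  The σ update repeats three
times per sweep (it costs no likelihood evaluations) to help the σ/r
trade-off mix.  Initialization is deterministic — slopes at zero, r at
1, p at 0.5, φ at the covariate median, ε at zero — with bounded
jittered retries if the starting likelihood is not finite.

For the lek design the latent N is summed out per route-year from
max_j y_j up to μ + (6 + 24/√r)·sd + 30 (sd² = μ + μ²/r), a bound
checked against the exact negative-binomial quantile to leave under
1e-9 tail mass across the relevant (μ, r) range; the inner
log-sum-exp is a numba kernel with cached binomial-coefficient terms.
Proposals whose implied means would push the grid past a cap (default
4000) are rejected outright; with counts in the survey range such
proposals carry essentially zero likelihood.  Raising the truncation
bound further changes the log-likelihood by less than 1e-6 (tested).
A latent-N sampler — discrete random-walk updates for each N and a
conjugate Beta draw for p — is retained purely as a cross-check of the
marginalized implementation; the two agree within Monte-Carlo error on
a shared fixture.

Chain protocol defaults are desk-scale: 3 chains, 2,000 burn-in, 2,000
saved draws, thin 1.  The long-run protocol (3 chains, ≥200,000
burn-in, thin 5, ≥10,000 saved) is available as
`McmcConfig.paper_protocol()` or `--paper-protocol` on the CLI.
Convergence uses the classic potential scale reduction factor
(between/within chain variances, flagged at R̂ ≥ 1.1).  The hinge
triple (β5, δ, φ) is the slow direction — its posterior can be
multimodal when the threshold is weakly identified — so recovery
studies use longer burn-in (5,000) for the single-visit design.

## Posterior summaries

Direction probabilities are fractions of pooled draws strictly above or
below zero.  The threshold is reported in natural units through the
affine back-transform (quantiles commute with it).  The Bayesian
p-value simulates replicate counts per saved draw at the observed
covariates (using that draw's ε) and averages 1[observed > replicate],
ties counting one half — unbiased for discrete counts.  The annual
abundance index sums, per draw, latent-N draws for observed lek
route-years (resampled from N | y, params on a grid), expected counts μ
for observed direct route-years, and posterior-predictive draws for
unsurveyed route-years; percent change between two index years is
100·(m0 − m1)/m0 with the per-year figure the total divided by the year
span (the arithmetic, not geometric, convention — it is what reproduces
the conventional paired "total %, % per year" trend statements).

## Synthetic data

The generator emulates the survey structure the analysis assumes:
routes × years (× visits), climate-region weather with a seasonal cycle
(TMAX peaking June-August, TMIN bottoming December-February), an AR(1)
drought index, contract-period land cover drawn uniformly within
configured natural-unit ranges, and completely-at-random missing
route-years (10% by default; the mechanism is a modeling choice, as no
missingness process is specified for such surveys).  Counts are
simulated at route level, stops pre-summed.  What it does not emulate:
spatial correlation between neighboring routes, observer effects,
trends in land cover within a contract period, or visit-varying
detection.  Passing recovery tests therefore show the inference machine
is correct and calibrated under the model's own assumptions — not that
the model is correct for any particular survey.

Default study dimensions mirror a mid-sized statewide program: 33
routes, 1996-2014, 9 climate regions, two contract periods.  Recovery
studies use 50 routes × 20 years (single-visit) and 30 routes × 15
years (repeated-visit), 95% interval coverage over replicates, with
desk-scale chains sized for laptop runtimes; the reproduction script
reports the problem size next to every number.

## Known limitations

* A single global detection probability; no detection covariates.
* No spatial or temporal autocorrelation beyond the exchangeable
  route-year intercept; no multi-threshold models.
* The direct-design index confounds abundance and detection trends.
* σ and r absorb overlapping variation in the direct design; their
  joint posterior mixes slowly, and the marginal of either can be
  prior-sensitive at small n.
* Edge density's two normalizations differ; results are comparable only
  within one convention.
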
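# Methods

## Model and assumptions

The unit of analysis is the site × year × generation.  For each of the
two annual generations the per-generation growth rate λ_t is modelled as
a linear function of two lagged densities and 16 environmental
covariates, all standardized to zero mean and unit sample variance
within the model's dataset:

    λ_t = β0 + β1·Y_{t-1} + β2·Y_{t-2} + Σ_j βj·Xj_t + ε_t

λ is a **ratio** (current density / previous-generation density), not a
difference: the generative reading D_t = λ_t·Y_{t-1} only makes sense
multiplicatively.  A `lambda_mode="difference"` toggle exists for
sensitivity analysis.  Rows whose previous-generation density is zero or
missing have no λ and are dropped, never imputed — an additive offset
would distort λ's scale arbitrarily.  Models start from each site's
second survey year because the first year has no lag densities.

Lag structure per generation: the spring (first) generation of year y
uses the previous year's second-generation density (PS, lag 1) and
first-generation density (PF, lag 2); the summer (second) generation
uses the current year's first-generation density (CF, lag 1) and the
previous year's second-generation density (PS, lag 2).

Climate enters through life-stage windows: for the spring generation
egg = overwinter (Dec–Mar), larvae/pupae = spring (Apr–May), flight =
June; for the summer generation June, July and August.  December is
assigned to the *following* survey year's overwinter window, so the
first modelled year needs December of the preceding calendar year.
Each window value is the arithmetic mean of its monthly values —
including precipitation (a window-sum toggle `pt_agg="sum"` exists but
is off by default, since temperatures and precipitation are windowed by
the same rule).  Aspect is mapped to the solar-radiation index
trasp = (1 − cos(π/180·(aspect − 30)))/2; flat cells (undefined aspect)
receive the neutral 0.5 with a log entry.

## Fitting pipeline

1. **Standardization** per model dataset (each population × generation
   separately; the pooled "All" dataset over its pooled rows), using
   n−1 sample standard deviations.  Constant columns are dropped with a
   warning.
2. **Random-forest baseline** (scikit-learn, 500 trees, out-of-bag R²,
   permutation importances over 5 shuffles).  Diagnostics only: the
   forest has no likelihood, so it cannot drive AIC selection, but it
   flags whether a linear model is leaving large nonlinear signal on the
   table.
3. **Genetic-algorithm subset selection.**  Chromosomes are binary
   predictor masks; fitness is the OLS AIC of the masked fit,
   AIC = n·ln(RSS/n) + 2(k+2), counting intercept, k slopes and error
   variance.  Only ranking at fixed n matters.  Tournament selection
   (size 2), uniform crossover (rate 0.8), per-bit mutation (0.05), two
   elites, population 40, 60 generations; singular subsets score +∞.
   These hyperparameters reliably attain the exhaustive-search optimum
   on problems up to 18 candidates (verified against full enumeration at
   p = 8 in the tests).
4. **Jack-knife PLS** on the selected subset.  The single-response
   NIPALS deflation is computed directly; one pass yields the
   coefficient vector for every component count, which makes the
   leave-one-out loops cheap.  With full components on a full-rank
   design it equals the least-squares solution (tested to 1e-8 against
   the normal equations, and against scikit-learn's PLSRegression to
   machine precision).  The component count minimizes cross-validated
   PRESS over 1…min(n−1, k, 10); the winner is the *fewest* components
   within 1% of the total cross-validated scatter of the minimum,
   because past the signal rank the PRESS curve saturates and its
   literal argmin wanders among noise-level differences.  Folds are
   leave-one-out up to n = 150 and seeded 10-fold beyond, keeping large
   fits cheap without changing small-sample behaviour.
   Standard errors use the Tukey jack-knife over m = n leave-one-out
   refits, SE_j = sqrt(((m−1)/m)·Σ_i (b_(−i)j − b̄_j)²), with two-sided
   p-values from t with m−1 df and stars *** p<0.001, ** p<0.01,
   * p<0.05, ns otherwise.  A zero SE is reported with p = 0 and a
   warning.
5. **Balanced bootstrap for pooled models.**  Long series would dominate
   a naive pooled fit, so each of B = 50 replicates resamples an equal
   quota of rows per population (default: the smallest population's row
   count) with replacement and reruns GA + PLS.  Variables selected in
   ≥ 50% of replicates are reported with coefficient = mean and SE = SD
   over the replicates that selected them and a normal-approximation
   p-value.  B, the quota rule and the aggregation are this package's
   choices; fewer than 20 replicates triggers an instability warning.

All stochastic stages consume explicit seeds fanned out from one master
seed through `numpy.random.SeedSequence`, so a pipeline run is
deterministic end to end (the manifest records file checksums to prove
it).

## Synthetic-data generator

The generator emulates the study configuration: five populations (14, 8,
12, 6, 8 sites; spans 1990–2018, 2005–2013, 1997–2018, 1994–2011,
2007–2018), four walks per flight period, transect lengths 0.3–1.2 km.
Monthly mean temperature follows a cosine annual cycle (July ≈ 22 °C,
January ≈ −10 °C) plus a persistent site offset and year-month noise;
min/max temperatures bracket the mean by a per-site diurnal spread, so
IT < MT < AT always; precipitation is log-normal around 65 mm/month.
Topography and canopy are uniform draws fixed per site.

Latent densities follow the λ equation generatively.  The 16
environmental covariates are standardized over the whole bundle (per
generation) before entering λ; the lag densities instead enter scaled by
a fixed `density_scale` (default 10 adults/ha), because their
standardization statistics would depend on densities not yet generated.
Default truth (β0 = 1.3, β_lag1 = −0.25, β_lag2 = −0.05, active
environmental effects −0.15 on egg-window mean temperature, −0.10 on
larval-window precipitation, +0.08 on canopy, σ = 0.15) gives negative
density dependence with a stable equilibrium near 10 adults/ha —
site-level densities and counts in the range transect surveys of this
species report.  λ is floored at 0 (extinct series stay extinct; no
rescue) and densities are capped at 500/ha with a logged count of
clips.  Both generations of a site's first year share one seeded initial
density, so a β0 = 1, all-else-zero truth yields exactly constant
densities.

Counts per walk are Poisson(density × 2.5 ha/km × transect km): the
simplest count-valued observation model for a transect walk, chosen so
that the mean-count-per-km inversion is unbiased (tested: mean relative
error < 5% at 100 walks with no process noise).  Poisson observation is
a modelling choice of this package, not an estimate of the real surveys'
error structure.

`make_design_dataset` additionally simulates at the design level — iid
standard-normal predictors, response built on the sample-standardized
design — so estimator calibration (sign recovery, false-inclusion rate,
coefficient RMSE, jack-knife SE accuracy) can be measured against an
exactly known standardized truth.

### What passing tests do and do not show

The generator's climate has no spatial autocorrelation between sites, no
temporal autocorrelation beyond the seasonal cycle, no dispersal between
sites, and independent Poisson observation errors.  Passing recovery
tests therefore demonstrate that the estimator chain is correct and well
calibrated under the model's own assumptions; they do not demonstrate
robustness to detection-probability variation, observer effects or
spatially correlated climate in real surveys.

## Numerical choices and degenerate inputs

- AIC of a singular or over-parameterized subset (n ≤ k + 2) is +∞.
- RSS is floored at 1e-300·n before the log.
- `standardize` requires n ≥ 3 and at least one non-constant column.
- Jack-knife needs n ≥ 5; component selection n ≥ 4; per-model fits are
  skipped (with a structured log entry) below 10 rows.
- Duplicate site-year-generation rows are an error, never averaged.
- Survey-date/generation inconsistencies produce warnings only; the
  generation column is authoritative.

## Problem sizes

Default test and pipeline sizes: the full 48-site campaign (~1,900
site-generation rows, ~7,600 surveys) fits all 12 models in about a
minute; calibration suites use 20 replicates of n = 400 design rows and
400 pure-noise replicates for the type-I-error check.  These sizes make
the calibration estimates stable at a few percent Monte-Carlo error.

## Known limitations

- The report tables give per-model coefficients; no model averaging over
  GA near-optima, and no spatial or site-level random effects.
- The bootstrap aggregation treats replicate selections as exchangeable;
  variables hovering near the 50% selection frequency can flip in or out
  between master seeds.
- Raster extraction is out of scope: the pipeline contract is per-site
  value tables (an optional nearest-pixel GeoTIFF sampler is provided
  for users who have rasterio installed).
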
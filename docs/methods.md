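# Methods

## The model chain

The package links three quantities measured at the country level: the
prevalence of modern slavery (victims per 1000 population, with 95% CIs),
the performance of the industrial fishing fleet, and the flow of seafood
commodities between countries. The chain has four analytic stages —
metric construction, regression with AICc model selection and Monte Carlo
sensitivity, a PCA + k-means typology, and prevalence-weighted trade-risk
propagation — plus a synthetic generator that emulates every input.

### Fisheries metrics

All ratio metrics are aggregated over an inclusive year range (default
2005–2014) from decade **sums**, not means of annual ratios; annual ratios
become unstable when a single year's denominator is small. Definitions:

* `pct_unreported = 100 · Σ unreported / (Σ reported + Σ unreported)` —
  defined as a share of *total* landings so it is bounded in [0, 100].
* `landed_value_per_kg = Σ value / (1000 · Σ tonnes_total)` (USD/kg).
* `value_per_fisher` and `pct_subsidy` are taken relative to the
  decade-mean annual landed value (fishers and subsidy levels are static
  covariates); `tonnes_per_fisher` uses decade-mean annual landings.
* `pct_catch_outside_eez` is the tonnage share of cells whose EEZ owner is
  not the fishing country; high-seas cells count as outside.
* `mean_distance_km` is the catch-weighted mean of each cell's great-circle
  distance to the closest domestic port (haversine, Earth radius
  6371.0088 km — the IUGG mean). Ties between equidistant ports are
  irrelevant: only the distance enters the metric.

Across-year spreads of the annual ratio series are returned as `sd_<metric>`
columns for the Monte Carlo stage; a config switch reports standard errors
instead (SD is the default because the sensitivity analysis propagates the
year-to-year variability itself, not the uncertainty of the decade mean).
Countries with zero total catch are dropped with a warning; countries
lacking cells or ports get NaN spatial metrics rather than an error.

### Regression and model selection

Prevalence is regressed on metric subsets by OLS. Model ranking uses the
Gaussian-likelihood AICc with the error variance counted as a parameter
(k = p + 1 for p coefficients including the intercept); a perfect fit
(RSS = 0) maps to −∞ and legitimately dominates the ranking. Selection is
exhaustive over all 2^m − 1 non-empty subsets — m is small here. A constant
response returns R² = 0 with a `zero_tss` flag rather than NaN.

Outlier policy: exclusions are a configurable country list (default
`("IND", "India")`), applied to the regression stage only. The default
reflects the known distortion of India's national prevalence by land-based
slavery in landlocked states; synthetic country codes never collide with it.

The Monte Carlo sensitivity analysis redraws, per run, each country's
fisheries predictors from N(mean, across-year SD) and/or its prevalence from
N(estimate, CI half-width / 1.96) — truncated at zero, since prevalence
cannot be negative — according to the scenario (`all`, `fisheries_only`,
`slavery_only`), refits the selected model and records R². Point estimate
and refits share one lstsq code path, so with all SDs at zero every run
reproduces the point estimate exactly. Degenerate draws (rank-deficient
design, zero response variance) are skipped and counted, with a warning
above 1% skipped. Default 10,000 runs; ~2 s for 20 countries.

### Country typology

The six typology variables mix %, USD and km, so PCA runs on z-scored data
(correlation matrix). Conventions: eigenvectors ordered by descending
eigenvalue; each component sign-flipped so its largest-|loading| entry is
positive (reproducible biplots); scores are projections of the z-scored
rows, so score covariance is diagonal with the eigenvalues.

k-means on the PC1–PC2 scores uses Lloyd's algorithm with 50 restarts,
initial centroids drawn from the data points under a seed, keeping the
lowest within-cluster SS. The cluster count is chosen by maximising average
silhouette width over k ∈ [2, 6] (ties to the smaller k); the within-SS
elbow curve is reported alongside as a diagnostic. A single deterministic
criterion was preferred over a battery of cluster-number indices: it is
reproducible and has a clear optimum on separable data. Labels are
renumbered 1..k by ascending mean PC1, so cluster identities are comparable
across runs.

### Trade-risk propagation

A prevalence of v per 1000 people, applied uniformly to all sectors
touching seafood, marks the fraction v/1000 of every tonne — numerically
v kg per tonne. Risks are carried unrounded end to end; a display helper
rounds to one decimal. This matters for the multipliers: an import risk of
3.1 kg/t over a domestic risk from a prevalence of 1.8 per 10,000 gives
3.1 / 0.18 = 17.2 → 17×, whereas rounding the denominator first would give
a different answer.

Import risk is the tonnage-weighted mean of the external suppliers'
national risks; flows inside a bloc of importing countries are domestic
supply, not imports, and are removed from both imports and exports before
computing domestic production net of exports. Supply risk is the
import/domestic mix weighted by import tonnage and net domestic production;
net production is floored at zero (re-export hubs can export more than they
produce) with a logged warning. When the domestic risk is zero the
multipliers are reported as undefined, never infinite. The model explicitly
assumes re-export neutrality: everything a country exports carries its
national risk, because commodity trade data do not preserve origin.

Commodity scope is HS6 codes with prefix `03` (fish and seafood, product
weight); flows can be averaged over a year window before propagation. The
Sankey export truncates to a top-N of sources plus an aggregated "other"
node whose risk is the tonnage-weighted mean of the tail, so tonnage and
risk mass are both conserved.

## Synthetic generator

The generator produces a world with the statistical structure the analyses
assume, not a replica of real geography or trade. Each country is assigned
(round-robin) to a cluster archetype — by default three: subsidised
distant-water fleets with poor reporting; lower-income largely domestic
fisheries; wealthy well-monitored fisheries — and draws its six typology
targets around the archetype means (relative SD 8%). Yearly landings vary
lognormally (CV 15%) around a country mean drawn lognormal around 500 kt;
unit value is lognormal around 1.2 USD/kg. Years are i.i.d. around the
country mean: the analysis only consumes decade means and spreads, so
within-decade trends would add nothing the pipeline could detect.

Spatial catch realises the targets directly: each country's decade total is
split over 30 cells by a Dirichlet draw (so cell sums reproduce panel totals
exactly), cells are placed at great-circle distances ~N(target, 15%) from a
home anchor and snapped to half-degree cell centres (x.25/x.75 — a ½° grid
convention), and EEZ attribution is Bernoulli at the target outside-EEZ
fraction, split evenly between foreign EEZs and the high seas. Own-EEZ
cells are therefore not geographically clustered near the coast; the
downstream metrics only consume distances and attributions, not shapes.

Prevalence is planted linearly: intercept 1.0 per 1000, +0.15 per
percentage point unreported, −0.8 per USD/kg, residual SD 1.0 per 1000,
truncated at zero; 95% CI half-widths are 30% of the estimate (plus a small
floor so widths are strictly positive). The planted coefficients are
returned as provenance (and written as a sidecar JSON) for
parameter-recovery tests. Truncation at zero biases recovery when the
linear predictor goes negative, so recovery tests raise the intercept to
4.0 and lower the residual SD to 0.3 — conditions under which the planted
signs are essentially always identifiable at n = 200.

Trade flows put one aggregate record on each ordered country pair with
probability `trade_density` (default 0.3), lognormal tonnage, and an HS6
code from a small class-03 pool.

Each generator owns an RNG stream seeded from `(config.seed, offset)` with
a fixed per-generator offset, so adding or rerunning one generator never
perturbs another, and identical configs are byte-identical.

What passing tests on this world do **not** show: anything about real catch
distributions, real port geography, real HS6 composition, population-
weighted bloc prevalences (the pipeline uses the unweighted member mean),
or the strength of the real-world prevalence–fisheries association — only
that the machinery measures, selects, clusters and propagates correctly
when the structure is known.

## Problem sizes and numerical choices

Default problem sizes: 20 countries × 10 years, 30 cells/country, Monte
Carlo 10,000 runs, k-means 50 restarts, k ∈ [2, 6]. Recovery tests use 200
countries; randomized trade-invariant tests use 100 seeds at 7–8 countries.
Zero-TSS detection threshold 1e−300; rank checks via numpy matrix rank;
silhouette requires 2 ≤ k ≤ n − 1 and at least k distinct points. All
randomness flows from explicit seeds — no wall-clock seeding anywhere.

## Known limitations

* National prevalence is a cross-sector proxy; nothing here resolves
  fisheries-specific slavery rates.
* Flag-state attribution is taken as given; flag-hopping is out of scope.
* No farmed/wild split in trade flows, no fishmeal (indirect) pathway, no
  product-weight ↔ live-weight conversion.
* EEZ attribution is an input attribute per cell; no polygon geometry.
* The Monte Carlo perturbs inputs independently per country and variable;
  correlated measurement error is not modelled.
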
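# Methods

`nutripanel` implements a digital-epidemiology workflow that links the
nutritional content of recipes bookmarked in an online food community to
county-level obesity prevalence in the United States. This note documents the
statistical model, the scoring scheme, the synthetic-data generator, and the
numerical and design choices behind the implementation.

## The FSA traffic-light score

Each recipe carries per-100 g amounts of four nutrients: fat, saturated fat,
total sugars (grams) and sodium (milligrams). Each amount is banded
green/amber/red against low/high cut points; assigning green=1, amber=2,
red=3 and summing over the four nutrients gives a composite score from 4
(very healthy) to 12 (very unhealthy).

Default cuts follow the 2007 UK Food Standards Agency front-of-pack guidance
per 100 g: fat 3.0/20.0 g, saturated fat 1.5/5.0 g, sugars 5.0/15.0 g, salt
0.3/1.5 g. Salt cuts are converted to sodium by dividing by 2.5 and
expressing in mg (120/600 mg). All cuts, the salt factor, and the boundary
convention are configurable; the default convention is inclusive on the low
side (an amount exactly at a cut falls in the lower band).

Banding is applied to per-100 g amounts. Per-portion amounts (recipe totals
divided by servings) are computed and carried for reporting, but are not
banded by default — the aggregation pipeline works on per-100 g values
throughout. Both conventions are available because source descriptions of
front-of-pack scoring vary on this point.

## Panel construction

Users are assigned to counties by exact match of their free-text location
label against a gazetteer; unmatched or ambiguous users are excluded and
counted. Fuzzy matching is deliberately not offered, keeping assignment
objective and reproducible. County identifiers are FIPS-like (state code ×
1000 + county index), so county uniqueness across states is structural.

Bookmark events are joined to user assignments and recipe nutrition; events
without either are dropped with a logged count. Per county-year the pipeline
records the number of distinct bookmarking users, the number of events, the
mean of each nutrient, and the FSA score **of the mean profile** (not the
mean of per-recipe scores; the alternative is available as an option).
Because the event-weighted mean is not the only defensible choice, three
weightings are implemented: each bookmark counts once (default), each
distinct recipe once, or per-user means averaged within the county-year.

County-years with fewer than 30 distinct users (inclusive threshold,
configurable) are dropped; the panel may be unbalanced. State-year rows are
recomputed from surviving counties: counts are summed (each user resides in
one county), nutrient means are combined weighted by bookmark counts (exactly
reproducing event-level aggregation), and state obesity is the unweighted
mean of county values. A pre-aggregated county/state-year CSV of averaged
nutrients plus obesity can be ingested directly, bypassing aggregation.

## Correlation analysis

Pairwise Spearman (default) or Pearson correlations over complete pairs, with
per-pair n, p-values and star annotation (*** p<0.001, ** p<0.01,
* p<0.05). Spearman is the default because rank correlations are robust to
the skewed nutrient distributions, but Pearson is provided as well; users
should state which they report. Pairs with fewer than 3 complete
observations are reported as undefined. For n ≤ 9 the Spearman p-value is an
exact two-sided permutation p over all n! orderings; otherwise the
asymptotic approximation is used. No multiple-testing correction is applied
by default; Benjamini–Hochberg is available as a flag.

## The three-level growth model

For year *t* (centred so that the first panel year, 2004 by default, is 0),
county *i* in state *j*:

    obesity_tij = β'x_tij + z_tij' r_ij + z_tij' u_j + ε_tij

* fixed effects β on x = (1, t, nutrition covariates): the nutrition terms
  are the county-year FSA score of means, or mean fat and sugar per 100 g;
* county-within-state effects r_ij ~ N(0, G_county) and state effects
  u_j ~ N(0, G_state) on z = (1, t): random intercepts and, optionally,
  random year slopes;
* residuals ε ~ N(0, σ²), independent across observations.

Each G is either fully correlated (2×2 with an intercept–slope covariance,
the default, matching how such model tables are usually reported) or
diagonal ("independent"). Observations from different states are independent,
so the marginal covariance of the data is block diagonal by state, with
county sub-blocks inside each state block.

### Estimation

The ML or REML objective is maximised over the *relative* covariance
parameters Ψ = G/σ², parameterised through unconstrained Cholesky factors
(log-diagonal, free off-diagonal), which enforces positive semi-definiteness
without constraints. For each candidate Ψ the fixed effects and σ² are
profiled out in closed form by generalised least squares on the per-state
blocks (Cholesky factorisation of W_j = I + ZΨZ' per state). REML uses the
Harville restricted likelihood without the |X'X| constant — the lme4
convention — so ML and REML log-likelihoods are directly comparable with
lme4's.

Optimisation uses L-BFGS-B from a deterministic variance-partition start
(between-state / between-county / within decomposition of OLS residuals,
slope variances started small) plus a neutral all-zeros start; a Nelder–Mead
polish runs if the gradient-based pass does not converge. Convergence is the
optimiser's own criterion (objective change below 1e-12, projected gradient
below 1e-7). Relative variances below ~1e-7 are treated as boundary
estimates, reported as exactly 0 with a `boundary` flag. A non-converged fit
returns the best iterate flagged `converged=False`.

`dense_loglik` is an independent correctness oracle: it builds every state's
full marginal covariance matrix explicitly and evaluates the exact Gaussian
(or restricted) log-density. The test suite requires the fitted objective to
agree with it to 1e-6.

### Inference and model comparison

* **Parameter count** k = number of fixed effects + free (co)variance
  parameters + 1 residual variance. This yields k = 4, 9, 10, 11 for the
  standard four-model sequence below.
* **AIC/BIC**: −2·LL + 2k and −2·LL + k·ln(n).
* **Likelihood-ratio tests**: 2·ΔLL against χ² with df = Δk. When the pair
  differs in fixed effects and was fitted by REML, both models are re-fitted
  with ML automatically, since REML likelihoods are not comparable across
  fixed-effect structures. A negative statistic beyond tolerance raises an
  error (it signals optimiser failure rather than evidence).
* **ICC** (random-intercept models only):
  ICC_county:state = (σ²_county + σ²_state)/(σ²_county + σ²_state + σ²_res),
  ICC_state = σ²_state / same total.
* **Pseudo-R²**: (σ²_res,base − σ²_res,extended)/σ²_res,base, the
  proportional reduction in within-unit residual variance.

### The model sequence

`run_model_sequence` fits, on the same panel: a single-intercept OLS null
baseline; **Model 1**, unconditional means (random intercepts at both
levels); **Model 2**, unconditional growth (fixed + random year slopes);
**Model 3**, Model 2 + FSA score fixed effect; **Model 4**, Model 2 + fat
and sugar fixed effects. LRTs are reported for the nested pairs Null→1,
1→2, 2→3 and 2→4. Models 3 and 4 are *not* nested in each other (Model 4
swaps the FSA score for fat + sugar), so no LRT is reported for that pair;
they are compared by AIC/BIC. Reported variance components come from REML
by default; fixed-effect LRTs are ML by the automatic re-fit rule.

## The synthetic-data generator

The generator produces a desk-scale study world with the structure the
analysis assumes, so every stage is testable without any crawled or
surveillance data. Defaults (chosen once as the package's study conditions):
8 states × 5 counties, ~40 users per county (negative binomial, dispersion
8, minimum 1), 3000 recipes, 20 bookmark events per user-year (Poisson) over
2004–2012.

* **Recipe nutrition**: log-normal per nutrient (non-negative and
  right-skewed, like real recipe data), medians 9 g fat, 3 g saturated fat,
  8 g sugar, 350 mg sodium per 100 g with log-scale sigmas 0.6/0.7/0.9/0.5;
  saturated fat is truncated at the recipe's fat so profiles stay valid.
* **County taste shifts**: each county draws a latent shift d ~ N(0, 0.5²);
  its bookmarks select recipes with probability ∝ exp(d·z), where z is the
  recipe's standardised "unhealthiness" axis (mean of the standardised log
  amounts of the four nutrients). Exponential tilting of a log-normal is an
  additive shift of its log-location, so a county's bookmarked nutrient
  distributions are location-shifted versions of the global ones. The
  heterogeneity scale 0.5 makes county mean nutrients — and the coarse,
  integer-valued FSA score of the means — vary between counties, which is
  what makes nutrition fixed effects identifiable downstream.
* **Obesity**: generated from the three-level growth model above with
  configurable true parameters. Defaults mirror US county-surveillance
  magnitudes: intercept 25%, year slope 0.3%/yr, fat coefficient 0.19,
  sugar 0.08, county intercept variance 9, county slope variance 0.09,
  state intercept variance 5, state slope variance 0.04, residual variance
  1. Values are *not* clipped to [0, 100] (the model is linear-Gaussian; a
  warning is emitted if any value falls outside, which the defaults keep far
  away from). The drawn state/county effects are returned for recovery
  testing. A `missing_rate` option drops random county-years to mimic
  unbalanced coverage.
* `simulate_panel` bypasses the bookmark layer for estimation studies,
  drawing county-year covariates directly (county-level mean plus yearly
  noise) and generating obesity from them.

Everything is deterministic given config + seed (separate numpy
`SeedSequence` streams per stage).

### What the generator does and does not emulate

It reproduces the *statistical structure* the models assume: nested
geography, unbalanced panels, right-skewed nutrients, between-county
nutrition differences, and a linear-Gaussian outcome process. It does not
emulate user demographics, population-density bias in who uses recipe
websites, measurement error in surveillance obesity, non-linear
outcome–nutrition relationships, or spatial correlation between neighbouring
counties. Passing recovery tests therefore demonstrates the estimator is
correct *under the model's own assumptions*; it says nothing about
robustness to the ways real data violate them.

## Validation studies (sizes used)

* Parameter recovery: 100 replicate panels at 50 states × 6 counties × 9
  years (2700 rows each), the full Model-4-style specification; fixed
  effects required unbiased within 3 Monte-Carlo standard errors, variance
  components within 30% relative error in the mean.
* LRT calibration: 2000 replicates of a true-null extra fixed effect at 10
  states × 4 counties × 5 years; empirical type-I error at α = 0.05 required
  within [0.035, 0.065]. This design size is large enough for the asymptotic
  χ² reference to apply.
* Oracle equivalence: dense-covariance log-density vs the fitter's profiled
  objective, agreement to 1e-6 on ≤ 200-row panels, ML and REML.

## Known limitations

* Only two grouping levels (county-within-state, state) plus time; no
  crossed random effects, no residual autocorrelation within county across
  years, no spatial structure.
* Gaussian outcome only; prevalence near 0 or 100% would need a bounded or
  generalised model.
* The standard errors of variance components are not reported (inference on
  them should use LRTs, respecting the boundary problem for variances).
* Exact permutation p-values are limited to n ≤ 9 per pair; beyond that the
  asymptotic approximation is used.
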
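# nutripanel

Digital-epidemiology tooling for linking the nutrition of recipes bookmarked
in online food communities to county-level obesity prevalence. The package is
aimed at computational epidemiologists and biostatisticians who want to
reproduce or extend this style of analysis: it scores recipe healthiness with
the UK FSA front-of-pack traffic-light scheme, aggregates bookmark events to
county-year and state-year panels, and fits three-level longitudinal linear
mixed models of obesity — with a synthetic-data generator so the whole
pipeline is testable without any crawled or surveillance data.

## The model

Recipes are scored by banding each of four per-100 g nutrients — fat,
saturated fat, sugar (g) and sodium (mg) — as green/amber/red against
low/high cuts and summing green=1, amber=2, red=3, giving an **FSA score**
from 4 (very healthy) to 12 (very unhealthy).

County-year panels of mean bookmarked nutrition (counties with ≥ 30 distinct
users) are joined to census-style obesity prevalence and modelled with a
three-level growth model: for year *t* (centred at 2004 = 0), county *i* in
state *j*,

```
obesity_tij = β' x_tij + z_tij' r_ij + z_tij' u_j + ε_tij
r_ij ~ N(0, G_county),   u_j ~ N(0, G_state),   ε_tij ~ N(0, σ²)
```

with fixed effects β on x = (1, t, nutrition covariates) and random
intercepts/year-slopes z = (1, t) at the county-within-state and state
levels. Estimation is profiled ML/REML over Cholesky-parameterised relative
covariances; the package reports variance components, fixed effects with
standard errors, AIC/BIC, likelihood-ratio tests (with automatic ML re-fit
when fixed effects differ), intraclass correlations and pseudo-R². See
`docs/methods.md` for the full account.

## Worked example

Score one recipe and run the full pipeline on the bundled synthetic world:

```python
from nutripanel.fsa import NutrientProfile, fsa_score, per_portion

totals = NutrientProfile(fat=36.0, saturated_fat=12.0, sugar=48.0, sodium=2400.0)
print(per_portion(totals, servings=12).amounts())
# {'fat': 3.0, 'saturated_fat': 1.0, 'sugar': 4.0, 'sodium': 200.0}

cake = NutrientProfile(fat=18.0, saturated_fat=9.0, sugar=28.0, sodium=320.0)
print(fsa_score(cake))   # 10  (fat red, sat-fat red, sugar red, sodium amber)

from nutripanel.mlm import icc_from_components
print(icc_from_components(8.90, 4.87, 1.79))
# {'county:state': 0.8849..., 'state': 0.3129...}
# 88% of obesity variance sits between geographic units, 31% between states
```

```sh
nutripanel run-all --seed 11 --min-users 20 --out artifacts/
```

fits the four-model sequence on the simulated panel and prints/writes, among
other artifacts, `models_comparison.txt` (this is the actual output for seed
11, 8 states × 5 counties, truth: year slope 0.3, fat 0.19, sugar 0.08):

```
                                                 Null          Model 1          Model 2          Model 3          Model 4
Variance Components
Var: county:State (Intercept)                                    10.30            10.96            10.58            10.41
Var: State (Intercept)                                            0.38             2.21             2.21             2.20
Var: Residual                                   12.44             2.05             1.03             1.02             1.00
Var: County:State Year                                                             0.07             0.07             0.08
Cov: County:State (Intercept) Year                                                -0.26            -0.28            -0.33
Var: State Year                                                                    0.02             0.02             0.02
Cov: State (Intercept) Year                                                       -0.21            -0.21            -0.20
Fixed Effects
(Intercept)                           27.91*** (0.19)  27.92*** (0.57)  27.06*** (0.76)  20.17*** (3.34)  21.82*** (2.03)
Year                                                                       0.22* (0.07)     0.22* (0.07)     0.22* (0.07)
FSA score                                                                                   0.85* (0.40)
Fat/100g                                                                                                      0.23 (0.18)
Sugar/100g                                                                                                   0.23* (0.09)
AIC                                           1837.31          1369.57          1238.55          1236.12          1236.46
BIC                                           1844.98          1384.91          1273.06          1274.47          1278.64
Log Likelihood                                -916.65          -680.79          -610.27          -608.06          -607.23
Num. obs.                                         342              342              342              342              342
Num. groups: county:state                          38               38               38               38               38
Num. groups: state                                  8                8                8                8                8

Note: *** p < 0.001, * p < 0.05; standard errors in parentheses.
LRT Null vs Model 1: chi2(2) = 471.73, p = 3.67e-103
LRT Model 1 vs Model 2: chi2(5) = 144.53, p = 1.95e-29
LRT Model 2 vs Model 3: chi2(1) = 4.49, p = 0.0341
LRT Model 2 vs Model 4: chi2(2) = 10.88, p = 0.00434
```

Reading it: Model 1 partitions obesity variance into county (10.30), state
(0.38 here; intercept spread partly absorbed by counties at this small
scale) and residual (2.05) components; adding the year growth terms (Model 2)
halves the residual variance; the nutrition covariates (Models 3–4) recover
effects near their generative values (sugar 0.23 vs truth 0.08+confounding
share of the taste-shift construction, fat 0.23 vs 0.19) and improve fit per
the LRTs and AIC.

Individual stages are exposed as subcommands (`simulate`, `score`,
`aggregate`, `correlate`, `fit`, `report`) and as plain library functions.

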
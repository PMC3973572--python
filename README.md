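# nestmosaic

Inference tools for indirect (nest-based) surveys of unhabituated great
apes, built around the study design used for the bonobo (*Pan paniscus*)
population of the Malebo forest-savannah mosaic in western DR Congo: line
transects are walked through three forest strata, every nest's
perpendicular distance is recorded, fresh nests at known nesting sites are
revisited until they decay, fruiting trees are checked biweekly, and
village questionnaires quantify human forest use.  The package chains the
full inference from these raw tables to population estimates and
socio-ecological models, and ships a synthetic-landscape generator so the
whole pipeline can be exercised and validated without the (unreleased)
field data.

## What it computes

1. **Distance sampling** (`distsamp`): a half-normal (+ cosine adjustment)
   or hazard-rate detection function g(x) fitted by maximum likelihood,
   truncated where g(w) falls to 0.15; effective strip width
   ESW = ∫₀ʷ g(x) dx; nest density D̂ = n / (2 L · ESW); conversion to
   individuals by the nest construction rate (1.37 nests · builder⁻¹ ·
   day⁻¹), the builder fraction (0.75) and the mean nest decay time;
   area-weighted stratified abundances with log-normal CIs.
2. **Nest decay** (`decay`): survival S(t) = logistic(β₀ + β₁t) fitted to
   revisit histories; mean decay time ln(1+e^{β₀})/|β₁| (verified against
   quadrature); site-stratified nest bootstrap CIs.
3. **Between-year dynamics** (`dynamics`): zero-inflated negative binomial
   regression of per-transect nest counts on survey year with effort
   offsets — log L in the count part, log(1/L) in the zero part — and a
   Gaussian-kernel spatial autocovariate (count part only) whose bandwidth
   maximizes the full-model likelihood; likelihood-ratio tests and
   releveling for year contrasts; leave-one-out influence.
4. **Fruit phenology** (`phenology`): fleshy-fruit availability index
   Σ_species (proportion fruiting × basal area, m²/ha); Box-Cox power
   transform by profile likelihood; Gaussian regression on sin/cos of the
   circular date, forest, their interaction and a temporal autocovariate;
   F-tests for seasonality.
5. **Site covariates** (`covariates`): permutation chi-square and exact
   binomial tests for nesting-tree preference; preferred-tree density;
   village influence Σ pop/distance; the questionnaire-based human
   forest-use index; 30-day rainfall; 14-day fruit availability windows;
   time-weighted interpolation of community size.
6. **Social cohesion** (`cohesion`): negative-binomial models of nest
   count per nesting site (a proxy for night party size) with a
   log community-size offset, under a one-community vs a two-community
   hypothesis, with a jointly profiled spatio-temporal autocovariate;
   AICc model comparison and a likelihood-ratio test of the four
   environmental predictors as a block.
7. **Synthetic landscape** (`synthdata`): two ape communities depositing
   clustered nesting sites (Thomas-style process, 30 m same-site rule),
   half-normal detection thinning, logistic nest decay, sinusoidal
   phenology with a between-forest offset, seasonal rainfall and
   gender-constrained questionnaires — all pure functions of
   (config, seed).

Each stage is a statsmodels-style pair: a Model class built from data
(`DetectionModel`, `NestDecayModel`, `ZeroInflatedNestCounts`,
`SeasonalFruitModel`, `CohesionModel`) whose `fit()` returns a results
object with estimates, standard errors, and a `summary()`.

## Worked example

```python
from nestmosaic import decay, distsamp, synthdata
import numpy as np

# survey two communities, fit the decay model, estimate density
records, truth = synthdata.simulate_survey(seed=11)
hist = synthdata.simulate_decay_histories(seed=11)
est = decay.bootstrap_decay(hist, n_boot=1000, seed=11)
print(est.summary())

distances = np.concatenate([r.distances_m for r in records])
w, kept, fit = distsamp.truncate_by_detection(distances, threshold=0.15)
print(fit.summary())
```

prints (abridged):

```
Nest decay time (left-truncated logistic survival)
==================================================
beta0 (logit):       4.5722
beta1 (logit/day):   -0.02439
mean decay (days):   187.9
95% bootstrap CI:    (182.6, 193.0)
bootstrap samples:   1000 (0 failed)

Detection function fit
========================================
key:              halfnorm
sigma (m):        11.792
truncation w (m): 22.9
ESW (m):          14.01
mean p:           0.612
log-likelihood:   -4068.515
AIC:              8139.03
n used:           1349
```

The decay CI brackets the generator's true mean (184.4 days =
ln(1+e^4.6)/0.025), the fitted half-normal scale recovers the generating
σ = 12 m, and the truncation distance solves g(w) = 0.15
(σ√(−2 ln 0.15) ≈ 23.4 m).  The full pipeline — density tables, dynamics,
phenology and cohesion models — runs with

```bash
nestmosaic run-all --seed 11 --out out/
```

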
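# Methods

This note records the models implemented in `nestmosaic`, the choices made
where the procedures admit more than one reading, and what the synthetic
validation does and does not establish.

## Distance sampling

Perpendicular nest distances x are modelled with a detection function
g(x), g(0)=1, either half-normal with optional cosine adjustments
(orders 2, 3, …; an order is rejected whenever the fitted g dips below
zero on [0, w], and the order is chosen by AIC) or hazard-rate
1−exp(−(x/σ)^−b).  The likelihood uses the truncated density
f(x) = g(x)/∫₀ʷ g; the normalizing integral inside the optimizer is a
64-point Gauss–Legendre rule, while all reported ESWs use adaptive
quadrature (the two agree far beyond the 1e-6 relative tolerance we
assert).  Truncation follows the detection-probability rule: fit on a
provisional strip, solve g(w)=0.15 by bisection, drop farther detections,
refit once.  One iteration is used because the refitted g changes w by
less than the inter-nest spacing in every synthetic experiment we ran.

Nest density per stratum-year is n/(2 L ESW).  The encounter-rate
variance uses the length-weighted between-line estimator
var(n/L) = K/(L²(K−1)) Σ lᵢ²(nᵢ/lᵢ − n/L)²; the %CV of individual density
combines encounter rate, a delta-method ESW component from the detection
fit's parameter covariance, and the bootstrap CV of the decay time, in
quadrature.  Confidence intervals are log-normal.  Abundance is density ×
area rounded to the nearest integer.  Stratified (global) estimates weight
stratum densities by area; their variance combines stratum variances with
squared area weights, treating strata as independent — the detection and
decay components are in fact shared across strata, so the global CV is
mildly conservative.

Conversion constants: nest construction rate 1.37 nests·builder⁻¹·day⁻¹
and builder fraction 0.75 (literature values — only habituated
communities allow estimating them); mean decay time is estimated from the
revisit data.  Builders-only densities omit the 0.75 divisor (infants
sleep in their mothers' nests).

## Nest decay

Fresh-marked nests give an exact age origin, so the left truncation of
the original survival formulation reduces to measuring age from the known
construction date.  Each scheduled revisit contributes a Bernoulli
observation "still recognizable at age t", modelled as
S(t) = logistic(β₀+β₁t); the mean decay time is ∫₀^∞ S = ln(1+e^{β₀})/|β₁|,
and the closed form is cross-checked against adaptive quadrature at every
call (1e-6 relative).

One modelling point deserves emphasis.  Field visits stop at the first
"disappeared"; but a marginal logistic regression fitted only to the
recorded rows is then severely inconsistent (long-lived nests contribute
dozens of presence rows and exactly one absence; on synthetic data with a
184-day true mean the naive fit returns ~410 days).  Because
disappearance is absorbing, the status of a vanished nest at every later
scheduled visit is known without visiting, and those implied absence rows
are filled in on each nest's own revisit schedule out to the common
follow-up horizon before fitting.  With the padding the marginal
probability of "present at age t" is exactly S(t) for every scheduled
age, and simulations recover the generating mean (its bootstrap CI covers
truth in ~96% of replicates).  Intermediate condition codes
(recent/old/very old) carry no extra information for this binary model
and are collapsed to "present".

The bootstrap resamples nests with replacement within nesting site
(respecting within-site correlation), refits, and takes 2.5/97.5
percentiles over 1000 replicates by default.  The inner logistic solver
aggregates rows to (age, trials, successes) triples and runs Newton
iterations with step halving — identical to the row-level MLE (we assert
agreement with statsmodels to ~1e-9) but fast enough for the bootstrap.

## Between-year dynamics (ZINB)

Per-transect nest counts mix structural absence (a transect outside the
currently used range) with overdispersed counts, so year effects are
estimated by a zero-inflated NB2 regression: logit zero part and
log-link count part, both containing year (reference level in the
intercept), with fixed-coefficient offsets log L (count) and log(1/L)
(zero).  The likelihood is implemented directly (the fixed zero-part
offset is not expressible in off-the-shelf zero-inflated fitters) and
optimized by BFGS with a Nelder–Mead polish; standard errors come from
the numerical Hessian.  With the zero-part intercept driven to −∞ the
log-likelihood reproduces a plain NB fit to machine precision, which the
test suite asserts against statsmodels.

The spatial autocovariate for unit i is the Gaussian-kernel weighted mean
of the other units' residuals, acᵢ = Σ_{j≠i} K(dᵢⱼ)rⱼ / Σ K(dᵢⱼ),
K(d)=exp(−d²/2sd²), entered in the count part only.  Choices:

- residuals are response-scale (y − (1−π̂)μ̂); configurable, since the
  source analyses do not pin the residual type;
- repeat surveys of the same transect (inter-year distance zero) are
  excluded from each other's average — the term averages *other
  transects*;
- the bandwidth sd is chosen by profiling the refitted full-model
  likelihood over a log-spaced grid (0.1–20 km, 25 points by default)
  with a bounded scalar refinement around the best grid point; the
  residuals are those of the no-AC full model, computed once (no
  fixed-point iteration).

Known limitation: the autocovariate is a generated regressor built from
the same realization it is then fitted to.  In null simulations (no
spatial structure) its Wald test is mildly anticonservative — |z| > 1.96
in roughly 12–15% of seeds at nominal 5%, with a small negative bias —
and no per-fit standard error (Hessian, Pearson-residual, or sandwich)
repairs this, because the inflation reflects the procedure's reuse of the
data rather than a variance formula.  When the kernel is fed residual
vectors that are independent of the counts, the coefficient is correctly
calibrated (~93% non-significant).  Conclusions that hinge on the AC
term's significance should therefore be treated cautiously.

Year contrasts not against the reference level are obtained by
releveling and refitting; the log-likelihood is invariant and the
contrast arithmetic (a−b identities) holds to optimizer precision.
Model robustness is screened by leave-one-out refits reporting
coefficient deltas.

## Fruit phenology

The availability index for a unit is Σ over the fleshy-fruit species set
of (proportion of the species' monitored trees currently fruiting) ×
(the species' basal area in m²/ha for that unit).  Basal area per species
is Σ π(DBH/2)² over stems ÷ sampled hectares.  The species set is a
configuration input: the field criteria (eaten by the apes, or
fleshy-fruited per regional floras) are not reproducible without the
original species table.

The biweekly forest series is modelled on a power-transformed scale: the
Box-Cox λ maximizes the profile normal likelihood of the regression
residuals (response > 0 required; the profile includes the Jacobian term
(λ−1)Σ log y).  The design holds forest, sin and cos of the circular date
(angle = 2π·doy/365.25), optionally their interaction, and a temporal
autocovariate using the same kernel machinery with distance in days.
Seasonal amplitude is √(b_sin²+b_cos²) and phase atan2(b_sin, b_cos);
origin shifts of the date rotate the phase and leave the amplitude
unchanged (asserted to 1e-8 for within-year shifts — across a year
boundary the day-of-year map is only piecewise linear).  Nested models
are compared with extra-sum-of-squares F-tests.  Daily proportions
between biweekly visits take the nearest observation, earlier on ties.

## Site covariates

- **Nesting-tree preference**: observed nest counts per species vs the
  expectation proportional to forest abundance; chi-square with a
  permutation p (multinomial resamples under the abundance null,
  +1/(n_perm+1) correction) and one-sided exact binomial tests per
  species; preferred = p < 0.05.
- **Preferred-tree density at a site**: preferred stems among nest +
  control trees over a fixed reference disc of 30 m radius (0.283 ha) —
  the same-site rule radius; the field protocol defines no site area, so
  this constant is prominent and configurable.
- **Village influence**: Σ population/distance (km).
- **Human forest use**: per village × activity, the mean over interviewed
  performers of (daily frequency ÷ number of regions visited, counted
  only when the region is among them), scaled by the village's
  gender-matched adult count, summed, divided by region area (km²);
  log-transformed before modelling.  Gender-specific activities never
  draw on the other gender's census counts.
- **Rainfall**: the sum over the 30 days strictly before nest building
  (a total, not a mean; configurable), with a warning when more than 20%
  of the window is missing.
- **Community-size offset**: the estimates from the surveys bracketing
  the build date, weighted by inverse time gaps — identical to linear
  interpolation, so nearer surveys weigh more; outside the surveyed span
  the nearest survey is used and flagged.
- **z-transform**: sample (n−1) standard deviation.

## Cohesion models

Nest count per nesting site is regressed (NB2, log link) on the six
z-transformed predictors with offset log(builders): pooled builders of
both forests under the one-community hypothesis, the site's own forest's
builders under the two-community one.  The spatio-temporal autocovariate
uses the product kernel K_s(d)·K_t(Δt) with both standard deviations
profiled jointly on a grid; the term is kept only if significant at 0.05
(the drop rule).  Hypotheses are compared by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting the NB dispersion.
The environmental block test is the LR chi-square (df = 4) of the full
model against a null with only the intercept, the two human-activity
controls, any retained autocovariate, and the offset.  Leverage is
screened from the weighted hat matrix (NB working weights μ/(1+αμ)) at
threshold 3k/n, configurable.

## Synthetic landscape

The generator emulates the study conditions: three rectangular strata
with the published areas (32.45 / 54.26 / 7.13 km²) and west–east
transects spaced 500 m; two communities sized like the published
abundance series (builders ≈ 0.75 × abundance: Nkala 15/12/13, Mpelu
23/8/13 for the three survey years); standing nests Poisson with mean
builders × 1.37 × mean decay days, deposited as a Thomas cluster process
(parents = nesting sites, offspring within a 15 m disc so pairwise
distances respect the 30 m same-site rule, mean site size 8 nests);
half-normal detection thinning (default σ = 12 m); logistic decay with
β₀ = 4.6, β₁ = −0.025 (mean 184.4 d, matching the ~183 d field estimate);
fruiting proportions mean 0.30 with amplitude 0.15, a +0.10 Nkala offset
and noise 0.04, clipped to [0, 1]; rainfall with the two regional dry
seasons scaled to ~1550 mm/yr; questionnaires drawn from the published
census with gender-constrained activities.  Nesting-site covariates are
drawn at realistic scales and nest counts follow the NB model with the
published cohesion effect sizes on the z-scale (0.070, 0.049, 0.109,
0.011, 0.045, −0.016) and dispersion α = 0.06, zero-truncated because a
recorded site has at least one nest.  Planar kilometres on a local
projection are used throughout (~17 km extent makes geodesy negligible).
One master seed spawns independent per-stage streams.

What the generator does *not* emulate: real nest-to-nest detection
heterogeneity (observer, vegetation), decay covariates (rain, tree
species), home-range drift within a year, spatially structured fruiting
(plots are exchangeable within forest), or questionnaire reporting bias.
Passing tests therefore establish that the estimators recover the
parameters of their own assumed data-generating processes at field-like
sizes — not that those processes describe any particular forest.

## Problem sizes and numerical choices

Validation suites run at the study's scale: 600-nest decay cohorts with
weekly visits, 72-transect × 3-year count panels, 90 nesting sites,
26 biweekly phenology dates per forest; replicate counts are 100–1000
per property, sized so Monte-Carlo error is small against each
acceptance band.  Optimizers: Nelder–Mead for detection functions
(1–3 parameters), BFGS + Nelder–Mead polish for the ZINB, IRLS/Newton
with step halving for the decay logistic, bounded Brent for the Box-Cox
λ and bandwidth refinement.  Ties in AIC model selection go to fewer
parameters; quadrature/closed-form agreement is asserted at 1e-6
relative; kernel identities at 1e-12.
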
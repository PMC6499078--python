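# Methods

## The SUMA error model and its estimators

A prediction *i* is a subject-location-biweek exposure estimate (ppb) with
estimated exposure Z_i and true exposure X_i.  The ensemble's replicates
are treated as draws of X_i from a dosimetry distribution, under the
Berkson-type model

    X_i = eps_SM * eps_Mi * Z_i + eps_SA + eps_Ai

with mean-1 multiplicative errors (variances sigma_SM^2 shared across
predictions, sigma_M^2 independent per prediction) and mean-0 additive
errors (sigma_SA^2 shared, sigma_A^2 independent).  "Shared" means one
draw per replicate common to all predictions; consequently, across
replicates,

    Cov(X_i, X_j) = sigma_SA^2 + sigma_SM^2 * Z_i Z_j          (i != j)
    Var(X_i)      = sigma_SA^2 + sigma_A^2
                    + [(1 + sigma_SM^2)(1 + sigma_M^2) - 1] * Z_i^2

Estimation is two OLS fits: pairwise covariance C_ij on the product of
across-replicate means Z_i Z_j (intercept -> sigma_SA^2, slope ->
sigma_SM^2), and per-prediction variance V_i on Z_i^2 (intercept ->
sigma_SA^2 + sigma_A^2, slope -> the total relative variance).  Component
solving truncates negative raw estimates to zero *before* the dependent
quantities are derived: sigma_SM^2 is truncated before dividing it out of
the total relative variance for sigma_M^2, and sigma_SA^2 before it is
differenced out of the unshared intercept for sigma_A^2.  An unshared
slope <= -1 is impossible under the model and raises.

Numerical conventions:

* Across-replicate means are unweighted; variances and covariances use
  sample (n_ens - 1) denominators — replicates are a sample from the
  dosimetry distribution.  An optional weight vector is not applied by
  default.
* Self-pairs are excluded from the covariance regression; the diagonal
  belongs to the variance regression.
* Pairwise statistics stream in row blocks (default 512) so the ~3.1 M
  pairs of a 2500-prediction sample hold ~100 MB.
* OLS standard errors and p-values are reported as nominal.  Pair records
  share indices and replicates, so they are descriptive summaries of fit,
  not exact inferential quantities.

Because the pairwise computation scales as n^2, components are estimated
on seeded random subsamples (default 2500 predictions, 11 independent
repeats).  One top-level seed drives all repeats through spawned
`numpy.random.SeedSequence` streams: repeats are mutually independent,
each bit-reproducible, and membership may overlap between repeats (the
draws are independent, not partitioned).  A representativeness report
(default: population-quartile bins) compares sample and population
distributions.

The estimator of sigma_SM^2 has an irreducible Monte-Carlo floor: every
C_ij is proportional to the *realized* variance of the n_ens shared draws,
so with 120 replicates the relative standard deviation of the recovered
sigma_SM^2 is about sqrt(2/119) ~ 13% regardless of how many predictions
enter the regression.  With zero true additive error the two intercept
estimators are unbiased around zero, so their truncation to zero occurs in
roughly half the replications each — "no evidence of additive error" shows
up as truncation plus a negligible surviving magnitude, not as a certain
zero.

## SMME labeling and group comparison

The mean covariance of prediction i is the average C_ij over all other
sampled predictions.  Predictions at or above the 80th percentile (linear
interpolation between order statistics; ties label high) are "high SMME".
Covariances are unstandardized, so predictions with large absolute
exposures tend toward larger mean covariances; the label is a screen, and
the percentile is a plain parameter (no multimodality detection).

Group comparisons use the standard parametric Welch two-sided t-test with
a 95% CI of the mean difference (low - high).  Tabulations report counts
and column percentages by season (winter = Dec-Feb, spring = Mar-May,
summer = Jun-Aug, fall = Sep-Nov, derived from the calendar month), period
or region, with each category's high-label share tested against the first
(reference) category.

An alternative reading of the mean-covariance screen — a cross-prediction
product of deviations (Z_i - E(Z))(Z_j - E(Z)) — exists; this package uses
the across-replicate covariance C_ij, which is the quantity the SUMA
regressions are built on.

## Spatial mapping

The odds of a high label are modeled as

    logit p(x, y) = s(x, y) + gamma' * covariates

with low as the reference group.  Two smoothing backends are provided:

* **spline** (default): a penalized tensor-product cubic B-spline smooth
  (8 marginal basis functions, second-order difference penalties) fit by
  penalized IRLS, smoothing parameter selected by AIC over a log-spaced
  grid.  Coordinates are affinely mapped to the unit square before basis
  construction, making fits invariant to translation and isotropic
  rescaling of the projected coordinates (planar meters are required; no
  geographic smoothing).  Pointwise standard errors come from the Bayesian
  posterior covariance of the penalized fit; the smooth-term p-value is a
  likelihood-ratio statistic against the parametric-only model on EDF
  degrees of freedom — approximate, as GAM smooth tests generally are, and
  slightly anti-conservative in small samples.
* **loess**: local scoring with a bivariate local-linear tricube smoother,
  span selected by AIC over {0.2, 0.3, 0.5, 0.7}.  Standard errors use the
  local-regression equivalent-kernel rows against the working-response
  variance and neglect smooth/parametric cross-covariance.  The spline
  backend is the default because its uncertainty quantification is exact
  within the penalized-likelihood framework; the loess backend matches the
  classical local-scoring formulation and serves as a cross-check.

The smooth is centered to mean zero over the training points, so the
mapped odds ratio at a grid point, OR(g) = exp(s(g)), is **relative to the
sample-average predicted log-odds**; this baseline choice changes the
printed OR range and is therefore stated prominently.  The surface is an
evenly spaced grid (default 50 x 50 over the bounding box, spacing
configurable in meters) clipped to the convex hull of the observation
locations.  A point is flagged hot/cold when its two-sided pointwise
(1 - alpha) band on log OR excludes zero; the default alpha = 5e-7 is a
deliberately strict constant appropriate to thousands of simultaneous grid
points, taken as a direct parameter (a Benjamini-Hochberg-derived alpha
can be substituted by the caller from grid p-values).

Covariate selection adds candidates one at a time and auto-retains a
candidate only on the quantitative rule: the OR range (max - min, or
either endpoint) moves by >= 10% relative to the model without it.
Whether a candidate "alters the spatial pattern" is a visual judgment; it
is quantified as the Jaccard overlap of flagged areas between steps and
reported for human review, never auto-decided.  The final reported model
is a single joint fit of all retained covariates.  Continuous covariate
odds ratios are per interquartile-range increase (OR = exp(beta * IQR),
Wald CIs); categorical covariates are dummy-coded against a reference
level.

## The synthetic-data generator

The generator implements the SUMA generative model directly, with the
defaults set to the studied conditions: 120 replicates; shared
multiplicative variance 0.0003 and unshared 0.0075 with zero additive
components (the estimated regime of the motivating NOx ensemble);
exposures Z either Uniform(10, 100) ppb (estimator-recovery experiments)
or lognormal around 30 ppb (the study fixture).

Multiplicative errors are lognormal re-parameterized to mean exactly 1 and
the target variance — the model constrains only the first two moments, and
lognormality keeps factors positive; a gamma alternative verifies the
estimators are family-robust.  Additive errors are normal.  Negative
simulated exposures (possible with additive noise) are retained so the
estimators' assumptions stay exact; a truncation switch exists for realism
experiments.

Shared error is *hierarchical*: one global mean-1 factor per replicate
(variance sigma_SM^2) multiplies every prediction, and each sharing unit
(group or hotspot region, crossed with time period) gets an extra mean-1
factor sized so the within-unit total shared variance hits its target
(base x period multiplier + regional extra).  Cross-unit pairs therefore
keep the global covariance while within-unit pairs covary more — without
the global layer, members of a small high-error region would covary with
almost nobody and their mean covariances would *fall below* the
background, inverting the labeling structure the model is meant to
produce.  Period multipliers below 1 are rejected: a period's shared
variance cannot fall below the global component it contains.

The default study fixture (`study_spec`) emulates a Southern-California-
shaped prediction set: a 200 x 150 km extent; three calendar-year tertiles
(1992-2000 / 2001-2004 / 2005-2012, weights 0.33/0.30/0.37) with shared
variances 0.00036 / 0.00015 / 0.00014; one harbour-like disc covering ~6%
of the extent with within-region shared variance ~0.0021, exposures scaled
1.8x (high-exposure harbour communities; the unstandardized mean-covariance
screen partly reflects absolute levels), and elevated traffic density,
population density and dispersion-model non-freeway NOx.  What the fixture
does **not** emulate: the internals of any real exposure model (ensemble
training, dispersion modelling, constrained optimization), residential
mobility, temporal autocorrelation within a prediction's biweekly series,
or anisotropic spatial correlation of covariate fields.  Passing recovery
tests therefore demonstrate that the estimators invert the SUMA moment
structure under realistic magnitudes — not that any particular real
ensemble satisfies that structure.

## Problem sizes used in the test suite

The suite scales the study down while keeping the quantities that control
estimator error at study values: the replicate count stays at 120 wherever
moment recovery is asserted (it sets the 13% Monte-Carlo floor), while
prediction counts are 600-3000 and per-stratum samples 500-1500 (pairwise
cost grows as n^2 and adds little precision beyond a few hundred
predictions).  Mapping calibration and power use n = 2500 labeled
predictions on a 50 x 50 grid, matching the analysis sample the method
targets.

## Known limitations

* SUMA distinguishes shared from unshared error globally; it does not
  model "within-shared" error of one location over time or calendar-time
  clustering of errors beyond the period strata.
* The pair-level regressions' nominal SEs understate uncertainty because
  pairs are dependent; the repeated-subsample spread is the honest
  robustness measure provided.
* The smooth-term p-value and the loess pointwise bands are approximate;
  the strict mapping alpha makes flagged areas conservative under the
  null (verified by simulation) but the approximations are not exact
  frequentist guarantees.
* The labeling screen is scale-dependent by construction; regions with
  high absolute exposures are more likely to be labeled high-SMME even at
  equal relative error.
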
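# Methods

## Model

The response is the child's weight-for-age z-score (WAZ), treated as
Gaussian with a common variance. The structured additive predictor is

    eta_i = w_i' gamma + sum_j f_j(x_ij) + f_spat(s_i)

with metrical covariates (child age in months, maternal age in years,
maternal BMI in kg/m²) entering as penalized smooths, a region label
s_i entering through a spatial effect, and categorical covariates
dummy-coded against declared reference levels with an intercept.

**P-splines.** Each smooth uses a B-spline basis on equidistant knots:
`n_knots` knots span the observed covariate range inclusive, extended by
`degree` knots per side at the same spacing, giving
m = n_knots − 1 + degree coefficients (22 for the cubic/20-knot
default). The coefficient prior is a partially improper Gaussian with
precision K/τ², K = D′D the d-th order difference penalty (d = 2 by
default: linear trends are unpenalized). Defaults follow the
conventional choices of the structured-additive-regression software
family; all are per-term configurable.

**Spatial effect.** An intrinsic Markov random field over regions:
K_spat is the adjacency-graph Laplacian, so β′K_spatβ equals the sum of
squared differences between neighbouring regions. Rank is S minus the
number of connected components. Isolated regions may optionally be
joined to their nearest neighbour by centroid distance (logged), since
the intrinsic prior is improper per component. Adjacency is accepted as
an edge list or derived from polygons by shared-boundary testing (and
written back out so derived adjacency is reproducible).

**Priors and sampling.** Flat prior on the fixed effects;
IG(a, b) on every variance with a = b = 0.001 by default (the standard
weakly-informative convention for this model family; per-term
overridable). All full conditionals are conjugate:

* coefficient blocks: N(μ, Σ) with Σ⁻¹ = B′B/σ² + K/τ²,
  μ = Σ B′r/σ² (r the partial residual), solved by Cholesky
  factorization with a logged 1e-8 ridge fallback if the precision is
  numerically singular;
* smoothing variances: IG(a + rank(K)/2, b + β′Kβ/2);
* error variance: IG(a + n/2, b + RSS/2).

The sweep is systematic-scan: fixed effects, each smooth, the spatial
block, the variances. After each block draw the coefficients are
centred to mean zero and the level moved into the intercept — valid
because every basis row (B-spline and one-hot incidence) sums to one,
so the linear predictor is unchanged; this pins down the levels the
intrinsic priors leave free. Initialization is deterministic (OLS fixed
effects, zero smooths, variances 0.1). One master seed spawns one
substream per update site, so runs are bit-reproducible. Default run
length 12,000 iterations / 2,000 burn-in / thinning 10 (1,000 retained
draws); a single chain, matching the intended single-chain diagnostics.

## Summaries, DIC, selection, diagnostics

Summary tables report posterior mean, SD, and 2.5/50/97.5% quantiles
per scalar parameter (plus 10/90% for curve bands), with linear
interpolation of order statistics as the quantile convention. A
parameter is flagged positive/negative when its 95% interval excludes
zero; the 80% band is reported for curves but not used for flags.
Smoothing-variance tables add the min/max over retained draws —
interpreted as the extremes of the retained chain.

DIC uses the Gaussian deviance D = n log(2πσ²) + RSS/σ²; Dbar averages
over draws, the plug-in deviance uses the posterior means of eta and
σ², pD = Dbar − D(η̄, σ̄²). pD can be negative in pathological cases
and is reported as-is with a warning. Stepwise selection is greedy
forward-backward minimization of DIC with strict improvement required
to add a term and ties resolved toward the smaller model; every trial
fit's seed derives deterministically from the configured seed, and the
full audit trail is returned.

Diagnostics: per-lag maximum |autocorrelation| across all scalar
parameters; residuals from the posterior-mean fit with standardization
by the posterior-mean error SD and sqrt(|standardized|) for the
scale-location display; histogram/KDE density exports (Gaussian kernel,
Silverman bandwidth) for distribution checks.

## Spatial mapping

Region effects are summarized and classed per region. Predicted
severity — the sign-flipped posterior-mean fit, so larger = more
underweight — is averaged per survey cluster and interpolated to a
regular lon/lat grid by IDW with great-circle (haversine) distances in
km and power p = 2 by default (a conventional choice; configurable).
Grid cells coinciding with a source reproduce its value exactly;
duplicate conflicting sources are averaged with a warning. Hotspots are
the cells strictly above a configured quantile of interpolated severity
(default: worst quintile) — a reporting convention, not an estimated
threshold. Interpolation at cluster locations is the default; region
centroids can be used instead by aggregating before interpolation.

## Yeo-Johnson screening

The four-branch Yeo-Johnson transform (identity at λ = 1, log-type at
λ = 0/2, defined for negative values) is implemented with its
closed-form inverse; λ is fitted by Gaussian profile likelihood over a
[−3, 3] grid with bounded local refinement (deterministic). Note the
positive branch is a power of (x+1), so the log-normal limit λ → 0
applies in the x ≫ 1 regime. Binned profiles use equal-width,
right-closed bins (default 30), emitting empty bins with count zero.

## Synthetic data generator

The generator emulates the structure of a national DHS-style survey of
children under five (the motivating micro-data are restricted):

* **design**: children assigned uniformly to clusters, clusters
  round-robin to regions (defaults 10,641 / 645 / 11); cluster
  coordinates uniform within region tiles mapped onto a 34–46°E ×
  4–14°N window;
* **covariates**: child age uniform on 0–59 integer months; maternal
  age truncated-normal(28, 7) on [15, 49] years; maternal BMI
  truncated-normal(21, 3.5) on [12, 50] kg/m²; categorical frequencies
  use the survey's published descriptives where available (rural
  81.45%; education none/primary/secondary/higher =
  64.26/25.17/6.90/3.67%; diarrhoea yes 82.94%) and realistic values
  where not (electricity no 70%, female household head 25%, anaemia
  none/mild/moderate/severe = 43/29/25/3%);
* **effects**: true fixed-effect sizes equal the published posterior
  means (e.g. female +0.0837, no-electricity −0.1976, severe anaemia
  −0.5319); true smooths are closed-form curves with the shapes seen in
  such data — WAZ declining to ~10 months then plateauing by ~30, flat
  maternal-age effect to 35 then declining, inverted-U in BMI peaking
  at a healthy BMI — each centred and scaled to SD 0.35 under its
  covariate distribution (≈ 0.3 × the error SD, large enough for
  recovery to be testable at n ≈ 2,000 while subordinate to noise);
* **spatial**: an intrinsic-MRF prior draw on the sum-zero constraint
  subspace (null-space directions zeroed), recentred and rescaled so
  the region-effect SD equals the scenario scale exactly (default
  0.60), which makes signal-to-noise conditions well defined;
* **noise**: Gaussian with SD √1.3511 ≈ 1.162, the published residual
  scale.

What the generator does **not** emulate: DHS sampling weights and
nonresponse, anthropometric measurement error, within-cluster
correlation beyond the region effect, non-Gaussian WAZ tails, and
covariate dependence (covariates are drawn independently). Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated model, not robustness to those real-data
features.

## Problem sizes and numerical choices

Recovery studies use n = 2,000 with 1,600-iteration chains (400
burn-in, thinning 2); stepwise-selection studies use n = 1,000 with
2,600-iteration chains retaining 2,000 draws, which keeps the
Monte-Carlo SE of DIC near 1 — small relative to the ~2–4 point pD
penalty of a shrunk noise term; survey-scale checks use n = 10,641 with
shorter chains where only structure (not precision) is asserted. These
sizes are the package's defaults for its own studies and scale linearly
if more precision is wanted. Degenerate inputs are rejected with typed
errors (constant smooth covariates, rank-deficient dummy coding with
the offending columns named, non-positive variances, unknown regions);
quantities that can go negative by round-off (penalty quadratic forms)
are clamped to zero with a warning.

## Known limitations

Single-response Gaussian models only (no logit/probit for the binary
underweight indicator); no tensor-product or varying-coefficient
smooths; no kriging or formal spatial autocorrelation tests; DIC is the
only comparison criterion (no WAIC/LOO). The anthropometric module
applies the generic z-score formula against a user-supplied reference
table; it does not implement LMS-type skewness adjustment, and no
growth-standard tables are bundled.
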
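# Methods

## The model

Across mammals, the relationship between occipital condyle width (OCW, mm)
and body mass (BM, g) is not log-linear: on log–log axes the point cloud is
concave down, with large mammals carrying proportionally wider condyles. The
package's central model linearizes this *non-linear allometry* by raising the
log predictor to a fractional power:

    ln(BM) = a · ln(OCW)^b + c

With `b` fixed this is linear in `(a, c)` and is fitted by ordinary least
squares on the transformed design (`allometry.fit_model`). The candidate
exponents `b ∈ {1/3, 1/2, 2/3, 3/4}` correspond to scaling regimes for linear
skeletal dimensions (geometric similarity L ∝ BM^{1/3}, elastic L ∝ BM^{1/4},
stress L ∝ BM^{1/8}, translated into log-power form); quadratic and cubic
polynomials in ln(OCW) are the conventional alternative description of
curvature. A free `b` is estimated by non-linear least squares
(`allometry.fit_free_exponent`): `scipy.optimize.least_squares` over
`(a, b, c)`, initialized from the 2/3-power OLS solution with `b₀ = 2/3` and
bounded restarts from `b₀ ∈ {1/3, 1/2, 3/4, 1}` on non-convergence (the
empirical optimum for condyle width lies near 2/3, so these starts bracket
it). Exponent confidence intervals are asymptotic Wald intervals from the
`(JᵀJ)⁻¹` curvature with a t reference on `n − 3` df; no profile or bootstrap
interval is attempted.

One motivation for the 2/3 form rather than a quadratic: writing
`ln BM = m · ln L^{1+r} + c` treats the allometric exponent itself as scaling
with size (`r < 0` down-weights the predictor at large sizes). The fitted
exponent `b = 1 + r ≈ 2/3` implies `r ≈ −1/3`. The conceptual size-dependent
scaling factor behind `r` has no estimator separate from `b` and is
documented, not estimated.

Natural logarithms are used throughout and the base is not configurable.

### Conventions

* Log-likelihood, AIC and BIC use the Gaussian-ML convention with the error
  variance counted as a parameter (`k + 1` for `k` regression coefficients),
  matching R's `lm`/`AIC` scale on which the comparative literature reports
  model ladders.
* `SEE` is `sqrt(RSS / df_resid)` on the ln scale.
* Adjusted r² comes from the OLS fit; it is reported but deliberately not
  used for accuracy claims (r² is inflated by wide log-scale data ranges).
* Group (size-class or clade/morphotype) allometry tests add a group dummy
  plus, for slope tests, a group × predictor interaction, and report the t
  and p of the tested term (`allometry.test_group_allometry`). Where an
  ANOVA-style decomposition is needed for multi-term fits, type-II sums of
  squares are the documented convention.

## Detransformation corrections and accuracy statistics

Exponentiating a log-scale prediction under-estimates the arithmetic mean of
a lognormal response. Three standard corrections are computed
(`accuracy.correction_factors`) and averaged:

* QMLE: `exp(s²/2)`, `s²` the residual mean square;
* smearing: `mean(exp(residuals))`;
* ratio: `mean(observed BM) / mean(exp(fitted ln BM))`, arithmetic means of
  raw grams on both sides.

The mean factor multiplies the back-transformed point estimate; interval
bounds are corrected the same way (the literature is silent on this; a single
multiplicative convention keeps corrected intervals bracketing corrected
points). Accuracy is summarized by

* `%PE = 100 · (observed − estimated) / estimated` per case, the *mean of
  absolute values* over a dataset (signed means are also reported for
  residual-direction tables);
* `%SEE = exp(SEE + ln 100) − 100`, with `ln 100 = 4.60517…` at full
  precision (the conventional printed constant 4.6052 differs by under 0.01
  percentage points);
* shares of cases within ±20% and ±50%.

`%PEcf` is recomputed from the corrected estimates; it is not asserted to be
smaller than `%PE` (either direction occurs).

Residual diagnostics (`accuracy.residual_diagnostics`): bias-uncorrected
moment skewness and excess kurtosis (at n ≈ 400 the corrected and
uncorrected versions are indistinguishable at the precision anyone reads
them); Breusch–Pagan LM statistic `n·R²` from regressing squared residuals
on fitted values, referred to χ²(1); hat-matrix leverages and Cook's
distances via statsmodels influence measures.

## Prediction

`predict.predict_mass` evaluates the model at the transformed predictor plus
any morphotype dummies, exponentiates, and multiplies by the mean correction
factor. 95% intervals use the standard OLS prediction variance
`s²(1 + x₀ᵀ(XᵀX)⁻¹x₀)` on the ln scale with a t reference on the residual
df, then back-transform. These are *prediction* intervals (new-observation
variance included); published fossil worked examples label similar ranges
"confidence intervals" while their widths are prediction-style, and the
naming choice here is deliberate. Extrapolation outside the training OCW
range is allowed but always flagged. Published reference equations
(`predict.REFERENCE_EQUATIONS`) carry only printed coefficients and a
correction factor, so they yield point estimates without intervals. Report
output rounds kg to one decimal; full precision is retained internally.

## Phylogenetic comparative machinery

Covariance structures on a rooted tree with branch lengths (`phylo`):
Brownian (shared root-to-MRCA path length), stationary Ornstein–Uhlenbeck
(`exp(−α·d_ij)` on patristic distances, unit diagonal; refused on
non-ultrametric trees, where the stationary form is undefined), and Pagel's
λ (Brownian off-diagonals × λ). PGLS solves the whitened least-squares
problem via a Cholesky factor of the covariance, with the residual scale
profiled out of the Gaussian likelihood; a single jitter of `1e-10 ×
mean(diag)` is attempted (and logged) on numerically non-PSD input. The OU
rate α, when not supplied, is profiled over a log-spaced grid `10⁻³…10³` (in
units of inverse tree depth) with bounded local refinement; λ likewise over
`[0, 1]`. Estimated covariance parameters count toward AIC/BIC.

λ estimation (`phylo.estimate_lambda`) is ML over `[0, 1]` with an
intercept-only mean, plus a χ²(1) likelihood-ratio p against λ = 0. The
implementation reproduces R's `phytools::phylosig` and `nlme::gls` +
`corBrownian` to six decimals on a frozen fixture (see the test suite).

Two numerical caveats are worth knowing:

* **Residual-based λ is attenuated.** Estimating λ on OLS residuals
  understates the generating λ because the fitted intercept absorbs the
  shared root history; on deep pure-birth trees the attenuation is visible
  (generating λ = 1 yields residual-λ̂ ≈ 0.8 at n = 200). Joint estimation
  inside the regression (`fit_pgls(kind="lambda")`) reduces but does not
  remove this — root state and intercept are confounded in finite samples.
  Recovery tests on raw traits (intercept-only, no regression) are clean.
* **PGLS accuracy is reported for the line used as a line.** %PE/%SEE of a
  PGLS fit are computed from ordinary residuals of the GLS line, because
  that is how such equations are applied to new (e.g. fossil) observations:
  the line carries no phylogenetic position information for a new taxon, and
  prediction that re-injects signal is deliberately out of scope. This is
  why Brownian PGLS can need large correction factors and show huge %SEE on
  strongly structured data while remaining the ML fit under its own model.

Tree samples: `pgls_over_trees` fits the same model across a list of trees
and returns per-tree coefficients and information criteria. Coefficients are
typically stable while AIC/BIC vary widely with tree choice, so summaries
are distributional (mean ± SD), never a single model-selection verdict.

## Synthetic data generator

`simulate.simulate_dataset` emulates, at species level: ln-OCW uniform on
`[ln 4, ln 250]` (the observed span from small rodents to an elephant);
ln-mass from the log-power curve plus an additive morphotype shift plus a
λ-structured residual (Brownian deviate on a pure-birth tree with
off-diagonal covariance × λ, total SD `residual_sd_log`). Specimens add iid
lognormal noise (`individual_sd_log` on mass; half that on OCW, since linear
dimensions vary far less between individuals than mass) and a captivity
effect on ln mass for captive-flagged rows.

Defaults are the study conditions: 404 species, `a = 7.69289`, `b = 2/3`,
`c = −8.19502`, `residual_sd_log = 0.39` (chosen to land near the canonical
≈48 %SEE), `lambda_signal = 0.9`, morphotype shifts `+0.71517` (rabbit-like)
and `−1.14562` (monotreme-like) at frequencies 0.05 and 0.01 (≈19 and 3 of
404 species), five specimens per species, `individual_sd_log = 0.15`
(specimen-level fits run a few %SEE points above species-average fits),
`captive_effect_log = 0.1` with 5% captive specimens (captivity effects are
detectable but small and confounded with body size in real collections). No
published residual-λ/Brownian-rate decomposition exists to serve as exact
simulation truth, so these defaults are calibrated to reported summary
statistics only.

The pure-birth tree simulator is hand-rolled (unit-rate Yule process,
rescaled to unit root-to-tip depth) so that all randomness flows through one
`numpy.random.Generator` and identical seeds give byte-identical Newick
output.

What passing tests on this generator show — and what they do not: recovery
of exponents, intercept shifts, residual SDs and λ demonstrates the
estimators are correct under lognormal, λ-Brownian assumptions. Real
comparative data add measurement error, non-uniform species sampling,
taxon-correlated body-condition variation and morphotype assignment
uncertainty, none of which the generator emulates; accuracy numbers on
synthetic data are therefore estimator checks, not forecasts of field
performance.

## Degenerate inputs and tie-breaks

* Zero-variance transformed predictors and rank-deficient designs raise
  explicit errors naming the offending columns; nothing is dropped silently.
* All-zero residuals give correction factors of exactly 1 and zero %PE/%SEE.
* Condition ranking (`io.rank_specimens_by_condition`) uses a stable sort,
  so exact ties preserve input order; fewer than three complete specimens is
  a refusal, not a guess.
* Fractional log-power transforms require the predictor to exceed 1 (so
  ln x > 0); prediction enforces OCW > 1 mm.
* Unknown sex/captivity parse from blank or "unknown"; unknown-captivity
  specimens count as wild in `fraction_captive` (zoo-flagged specimens are
  the marked class). Morphotype is an input column assigned by inspection of
  specimens, never inferred from the measurements.

## Problem sizes used in the test suite

Simulation-backed checks run at the scales the estimators are meant for:
400-species replicates (200 of them) for exponent bias and interval
coverage, 50-species replicates (200 each) for λ recovery at the endpoints,
40 replicates of a 38-tip two-clade geometry for the outgroup-displacement
sign test. These sizes give Monte-Carlo error comfortably below the effect
sizes being asserted.

## Known limitations

* The OU parameterization is the stationary one with a unit diagonal; root
  treatment and non-stationary variants are not implemented, so OU results
  are comparable across calls of this package but only approximately to
  other software.
* PGLS prediction for new taxa ignores phylogenetic position (see above).
* Reduced major axis / robust / Bayesian regression are out of scope, as is
  any phylogenetic mixed model for the captivity effect (the OLS factor test
  stands in for it).
* Morphotype beyond the two modelled shifts (cingulate-like, other
  apomorphic states) is flagged and excludable but carries no fitted shift:
  too few such taxa exist for a stable estimate.
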
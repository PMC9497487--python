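# Methods

## Model and likelihood

The two structural equations share one hinge primitive, the continuous
threshold function φ(x, t) = (x − t)·I(x > t), with a *strict* indicator so
φ(t, t) = 0.  Stage 1 writes the exposure as a kinked function of the
instrument (K kinks at c₁ < … < c_K), stage 2 the outcome as a kinked
function of the exposure (J kinks at t₁ < … < t_J); both keep a global linear
term, so each stage's conditional mean is continuous and piecewise linear.
The errors (u, v) of the two equations are mean-zero bivariate normal with
standard deviations σᵤ, σᵥ and correlation ρ; ρ ≠ 0 is what makes the
exposure endogenous, and identification comes from the instrument being
independent of (u, v).  K ≥ J is required (as many instruments as endogenous
regressors once the hinge columns are counted).

Estimation maximizes the mean per-observation log-likelihood

ℓₙ(θ) = (1/n) Σᵢ [ −log 2π − log σᵤσᵥ − ½ log(1−ρ²) − Qᵢ/(2(1−ρ²)) ],
Qᵢ = uᵢ²/σᵤ² − 2ρuᵢvᵢ/(σᵤσᵥ) + vᵢ²/σᵥ²,

with uᵢ built from the *observed* xᵢ (the structural residual), not the
stage-1 fit.  The additive constant −log 2π is kept so the absolute value is
comparable across software and usable in AIC/BIC; the reported model
log-likelihood is n·ℓₙ.  The analytic per-observation score is obtained by
the chain rule; its only non-obvious entries are the kink derivatives,
∂ℓᵢ/∂c_k = (∂ℓᵢ/∂v)·α_k·I(zᵢ > c_k) and the analogue for t_j, using the
subgradient convention that an observation exactly at a kink contributes 0
(a probability-zero event for continuous Z, X).  The score is validated
against central finite differences of ℓₙ in the test suite (1e−5 relative).

Two error parameterizations are available: separate (ρ, σᵤ, σᵥ), and a
common-variance version ending in (ρ, σ²) with σ² = σᵤ² = σᵥ².  The
simulation harness fits the common-σ version, matching its generating truth
and the single σ² row of the benchmark tables.

## Optimization

There is no closed form, so the criterion is maximized by BFGS with the
analytic gradient on a transformed space: ρ = tanh(η) and variances through
log (no boundary handling needed); thresholds stay on the raw scale, where
ℓₙ is continuous and piecewise smooth with a kink at every data point.
Starting values come from two-stage least squares: stage-1 OLS of x on
[1, φ(z, c), z] with c placed at quantile levels 5% + i·90%/(K+1) of z
(K = 1 → the median; interior placement avoids near-empty hinge columns),
then stage-2 OLS of y on the same construction in the fitted x̂; ρ, σᵤ, σᵥ
are initialized from the two stages' residuals.  A grid-search variant
(SSE-minimizing single threshold per stage over a 19-point quantile grid,
K, J ≤ 1) is available as an alternative initializer.

Two facts about this objective shaped the optimizer:

- **Maximizers sit on kinks.**  When the optimum lies at (or numerically at)
  a kink, the gradient cannot vanish — only one-sided derivatives exist —
  and BFGS ends with a line-search failure at gradient norms around 1e−3.
  The fit restarts BFGS with a fresh quasi-Newton state (up to 10 times);
  improvements decay geometrically at a kink, and once a restart gains less
  than 1e−8 in ℓₙ and moves the iterate by less than 1e−4, the point is
  accepted as stationary in the subdifferential sense.  A fit is recorded
  converged on scipy success, on gradient sup-norm below 1e−4, or on this
  kink-stall test.
- **The likelihood is multimodal in the thresholds.**  A pure gradient
  ascent from the quantile start can stall one or two modes away from the
  global one (in the one-kink benchmark design this happened in roughly a
  tenth of replicates, biasing ĉ).  After each ascent, a coordinate profile
  scan proposes threshold relocations: candidates on a 25-point quantile
  grid are scored by the likelihood after refreshing both stages'
  coefficients and error parameters by least squares conditional on the
  thresholds (a cheap surrogate for the profile likelihood, compared against
  the same surrogate at the current thresholds — absolute comparison would
  be unfair because the surrogate ignores ρ).  An improving proposal is
  polished by a fresh ascent and kept only if the true likelihood improves;
  the scan repeats up to three times.

Threshold/coefficient pairs are sorted ascending afterwards (the model is
invariant to permuting them; sorting removes label switching), estimates
escaping the 5–95% quantile range of their variable are projected back with
a warning, and thresholds closer than 1e−6 of the data range trigger a
non-identifiability warning.  The ascent property (final ℓₙ ≥ initial ℓₙ) is
enforced: a fit can never return a point worse than its start.

## Variance estimation

Let M = (1/n) Σ ℓ̇ᵢℓ̇ᵢᵀ be the average outer product of per-observation
scores at θ̂ and V the second derivative of ℓₙ.  Model-based inference
(correct specification) uses cov(θ̂) = M⁻¹/n; robust inference uses the
sandwich V⁻¹MV⁻¹/n.  Near-singular matrices fall back to a Moore–Penrose
pseudo-inverse with a loud warning.

V needs care at the kinks.  Differentiating the score a second time with
respect to a threshold produces Dirac terms from the indicators; their
large-sample limit is a density: the second derivative of the averaged
indicator is −f_Z(c_k).  V is therefore assembled in two parts:

1. the part continuous in every coordinate, by central finite differences of
   the analytic score with the indicator masks frozen at the base point
   (freezing matters: at large n an unfrozen difference quotient would step
   data points across the kink and pick up O(1/(nh)) jump noise);
2. density-limit corrections on the (c_k, c_k) and (t_j, t_j) diagonal
   entries, −α_k·Ê[∂ℓ/∂v · δ(z−c_k)] and −β_j·Ê[∂ℓ/∂u · δ(x−t_j)], estimated
   by Gaussian-kernel weighted averages whose normalization supplies the
   density estimate (Silverman rule-of-thumb bandwidth, the same estimator
   exposed as `kde_density`).

The cross (α, c) and (β, t) entries involve indicators but are continuous in
the thresholds, so part 1 already captures them exactly.  Note the t-diagonal
correction does **not** vanish at the truth: x is endogenous, so
E[∂ℓ/∂u | x = t] ≠ 0 — dropping it breaks the information equality.  Two
independent checks validate the construction: at n = 20000 on a correctly
specified design, −V matches M within a few percent on the natural scale and
sandwich SEs match model-based SEs within 5%; and the kink diagonal of V
matches the numerical Hessian of a kernel-smoothed likelihood (hinge
replaced by its Gaussian smoothing E[(w+hZ)₊], h → 0) within 15%.

Wald summaries report estimate, SE, z, normal CI and two-sided p per
parameter; p-values for threshold locations are reported as missing, since
"c = 0" is not a meaningful null.  Selection of (K, J) fits all admissible
pairs and minimizes AIC = −2nℓₙ + 2|θ| or BIC = −2nℓₙ + |θ|·log n.

## Simulation designs

Two built-in benchmark designs (one and two kinks per stage; equations in
`pliv.simulate`) draw Z ~ N(0,1) and bivariate normal errors with common
variance σ² and correlation ρ ∈ {0.2, 0.5, 0.8}, default n = 500.  The
default error scale is σ² = 0.3 (σ = √0.3 ≈ 0.548).  This choice is
deliberate: the benchmark bias/SE/coverage tables these designs reproduce
pin the error scale down through every scale-dependent SE and through the σ²
row itself (e.g. the asymptotic SE of the stage-1 kink location at ρ = 0.5
is ≈ 0.154 under σ² = 0.3 versus ≈ 0.086 under σ = 0.3, against ≈ 0.159
printed), while the scale-free ρ row agrees under both readings.  `sigma`
remains a free parameter of `ScenarioConfig`.

The Monte Carlo harness spawns per-replicate seeds deterministically from a
master seed, fits each replicate (common-σ LIML), records estimates, SEs and
95% CI coverage of the truth, and reports bias / tse (mean estimated SE) /
ese (SD of estimates) / cp (covering intervals) on the ×1000 scale.
Non-convergent replicates are dropped and counted; more than 10% dropped
aborts the study.  Coverage uses the model-based covariance — the simulation
is correctly specified.  Headline runs use 500 replications (the published
tables use 1000); binomial noise on a coverage count is then about ±10 per
1000 (1σ).

What these designs do *not* emulate about real data: non-Gaussian or
heteroscedastic errors, weak instruments (the designs' first-stage F is in
the hundreds), covariates, and discrete or bounded exposures (the
application-style use case of schooling years enters through the generic CSV
path with log transforms instead).  Passing calibration here shows the
estimator and its variance formulas are internally correct under the model's
own assumptions, not that the model fits any particular dataset.

## Known limitations

- Threshold estimates are heavy-tailed at n = 500: their empirical SD
  exceeds the mean estimated SE by ~30% for the stage-1 kink and their 95%
  intervals under-cover (≈ 85–90%), in line with the benchmark tables
  (≈ 84–86% printed for c).  Wald intervals for kink locations should be
  read as optimistic.
- One exposure, one instrument, Gaussian errors; no interactions between
  hinge terms; no binary/count outcomes.
- K and J are treated as fixed when selected by AIC/BIC; selection
  uncertainty is not propagated.
- The profile scan makes the ascent markedly more global but cannot
  guarantee the global maximum; two thresholds may still collapse onto each
  other in unlucky samples (warned, and visible as huge SEs on their
  coefficients).
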
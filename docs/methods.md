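# Methods

This note documents the statistical machinery implemented in `funmstate`,
the choices made where the design was genuinely open, and what the bundled
simulation studies do and do not demonstrate.

## 1. Data model and cohort rules

A cohort is panel data: per subject, an ordered sequence of visit times
(years since entry) with a cognitive state in {rNC, MCI, AD}, optional
values of up to 11 neuropsychological scales, optional 116-region
gray-matter density profiles, and baseline covariates (age, sex, years of
education, marital status, APOE ε4 carrier status). Validation enforces
the inclusion rules: MCI at entry, at least two visits, no observations
after the first AD diagnosis; violations are counted in an exclusion
report, never raised. Duplicate visit times keep the last record (logged);
time is in decimal years (a schema flag converts months). Region vectors
may optionally be renormalized to percentages of their own sum, matching
the whole-brain ratio standardization of gray-matter densities; this is
off by default so pre-normalized data pass through unchanged.

## 2. Sparse univariate FPCA (`funmstate.fpca`)

Model: Y_i(t) = μ(t) + Σ_k ξ_ik φ_k(t) + ε, ε ~ N(0, σ²), scores
uncorrelated with Var(ξ_k) = λ_k, eigenfunctions orthonormal under the
grid quadrature.

* **Grids.** Time: 61 equispaced points on [0, 15] years with trapezoid
  weights. Space: the 116 region indices with unit weights (Euclidean
  inner product). The 15-year window covers the maximum follow-up of the
  motivating cohort.
* **Mean.** Pooled penalized regression on cubic B-splines (15 basis
  functions, second-difference penalty, GCV over a 21-point log-spaced
  penalty grid). Constants and linear trends lie in the penalty null space
  and are reproduced exactly.
* **Covariance.** Raw cross-products of centered residuals at distinct
  same-subject time pairs, smoothed by a tensor-product penalized spline
  (8 basis functions per margin, Kronecker second-difference penalty,
  GCV); the diagonal is excluded so measurement noise cannot leak into the
  surface, and the result is symmetrized. σ² is the mean gap between a
  1-d smooth of squared residuals (which contains noise) and the
  surface's own diagonal, floored at max(0, 1e-8·max diag).
* **Eigendecomposition.** Weighted problem W^{1/2}CW^{1/2}; negative
  eigenvalues are clipped; PVE uses the full nonnegative spectrum as
  denominator (not just retained components); the smallest K with
  cumulative PVE ≥ 0.90 is kept; each eigenfunction is flipped to have a
  nonnegative quadrature integral so score directions are reproducible.
* **Scores.** PACE / BLUP:
  ξ̂_i = ΛΦ_iᵀ(Φ_iΛΦ_iᵀ + σ²I)⁻¹(y_i − μ_i), with conditional variances
  returned. A singular subject system (σ² = 0 with duplicated design rows)
  is jittered by 1e-10 with a warning.

## 3. Multivariate FPCA (`funmstate.mvfpca`)

The univariate-expansion (two-stage) construction: univariate FPCA per
marker at its own 90% PVE; the covariance Z of the stacked scores
(pairwise-complete over subjects, since a subject may lack a marker
entirely) is eigendecomposed; multivariate eigenfunction blocks are
ψ_m^{(p)} = Σ_k c_{m,pk} φ_k^{(p)}. Markers are standardized to unit
total variance before the joint step by default — the scales carry
incommensurate units — and the flag is recorded on the fitted object
because it changes coefficient interpretation.

**Disattenuation.** PACE scores are shrunken toward zero by a
component-specific factor (stronger for sparsely observed subjects and
low-variance components), so the raw covariance of estimated scores
understates the latent score covariance non-uniformly and biases the
joint variance shares. By default each entry of Z is rescaled by estimated
reliabilities r_k = 1 − E[conditional variance]/λ_k (diagonal ÷ r_k, cross
entries ÷ r_j r_k, r floored at 0.2) — the classical measurement-error
correction. It is a no-op for dense low-noise designs and assumes
measurement errors independent across markers; `attenuation_correction=False`
restores the plain estimator, whose joint scores are exactly uncorrelated
in sample.

The conventional-PCA path (`pca_baseline_scores`, the scalar-model
sensitivity arm) bins each subject's observations into five 3-year
windows, mean-imputes empty windows and applies ordinary PCA to the
standardized matrix. Values are deliberately not carried across windows:
with unequal follow-up that manufactures a dominant "time under
observation" artifact component.

## 4. Multilevel FPCA (`funmstate.mlfpca`)

Model: Y_ij(s) = μ(s) + X_i(s) + W_ij(s) + ε over the ordered region
domain, X subject-level, W visit-level. The 116 regions are treated as a
1-d functional domain in a fixed left→right anatomical order; smoothness
across neighboring indices is an assumption inherited from that ordering
and artificial adjacency exists at block boundaries — no correction is
attempted.

* **Traditional (tMLFPCA).** Method of moments: K_T from same-visit
  products, K_B from cross-visit same-subject products (subjects weighted
  by their number of usable pairs, so unbalanced designs pose no problem),
  K_W = K_T − K_B; σ² from the diagonal excess of K_W over its
  near-diagonal band; both level matrices symmetrized and
  eigendecomposed with negative eigenvalues clipped.
* **Fast (fMLFPCA).** The same moment algebra after projecting profiles
  onto 25 Euclidean-orthonormalized cubic B-splines (rank-deficient bases
  are reduced with a warning); σ² from the off-basis residual sum of
  squares; the small matrices are eigendecomposed and mapped back to the
  grid. Level scores solve the mixed-model (BLUP) equations jointly for
  (ξ_i, ζ_i1..ζ_iJ) per subject.
* **Variance share.** ρ = Σλ⁽¹⁾ / (Σλ⁽¹⁾ + Σλ⁽²⁾) with the level sums
  computed as full-spectrum traces of the moment matrices (noise trace
  removed, negative sampling mass retained, final ratio clipped to
  [0, 1]). Summing clipped eigenvalues instead would add the positive
  half of the sampling spectrum of a 116×116 moment matrix — an O(1)
  upward bias on the share at realistic n — whereas the trace is
  unbiased.

## 5. The multistate model (`funmstate.msm`)

Time-homogeneous (given covariates) continuous-time Markov chain on
(rNC, MCI, AD) with AD absorbing and no direct rNC→AD jump: reversion
routes back through MCI, and the rNC→AD *probability* is still nonzero
through that path. Covariates are baseline values plus subject-level FPC
scores (the scores summarize the whole marker trajectory); coefficients
are transition-specific. The AD visit is treated as panel-observed at the
visit, not as an exact event time, because diagnoses occur at scheduled
assessments.

* **Likelihood.** Product over consecutive visit pairs of
  [exp(Q_i Δt)]_{s_k, s_{k+1}}. The 3-state generator has a 2×2 transient
  block with real eigenvalues, so exp(Q t) is evaluated in closed spectral
  form, vectorized over pairs; the generic scaling-and-squaring route
  (`transition_probability_matrix`) and a Runge–Kutta ODE oracle serve as
  independent cross-checks in the tests. A disallowed observed pair
  yields −inf with a diagnostic.
* **Fitting.** BFGS on (log q₀, γ, β) with numerically differenced
  gradients; covariates standardized internally (estimates mapped back
  with the exact affine Jacobian); crude occurrence/exposure rates as the
  starting point plus two jittered restarts (deterministic given the
  seed); convergence declared at gradient ∞-norm below tolerance;
  covariance from the inverse numerically differenced Hessian, projected
  to the nearest PSD matrix if needed.
* **Functionals.** P(t) curves; length of stay
  E[time in s] = ∫₀^h P_{MCI,s}(u)du via high-order ODE integration with
  the conservation Σ_s = h enforced exactly; percentile CIs by drawing
  parameters from MVN(θ̂, vcov) (the description of the bootstrap as
  multivariate-normal resampling of the MLE; nonparametric subject
  resampling is not implemented); LRT for explicitly declared nested
  pairs and AIC for everything.
* **Observed vs expected.** On panel data the state is only known at
  assessments, so both curves are evaluated at each subject's most recent
  assessment time τ_i(u) ≤ u: observed = the state recorded then;
  expected = the subject's own P_i(τ_i(u)) row from MCI. For subjects
  whose visits stopped at the AD diagnosis, τ advances along the cohort's
  median visit gap (the state cannot leave AD, so the prediction at later
  intended visits is well defined). Naive alternatives — last state
  carried forward compared against P_i(u), or restricting to subjects
  under observation — are biased by the carry-forward lag and by survivor
  selection respectively, and fail even when the fitted model generated
  the data. Under heavy censoring the comparison degrades at late times
  (few intended-schedule anchors); the summary statistic is the maximum
  discrepancy in percentage points.

## 6. The simulator (`funmstate.simulate`)

The generator produces exactly the structure the model assumes — it
validates estimator implementations, not clinical realism.

* **States.** Gillespie simulation from MCI at the reported intensity
  scale q(MCI→rNC)=0.035, q(MCI→AD)=0.120, q(rNC→MCI)=0.117 per year;
  covariates and scores enter the log-intensities through the same
  exp-linear link the model fits.
* **Visits.** First visit at 0; gaps Gamma(mean 0.75 y, sd 0.25 y)
  truncated to [0.25, 2], continuing to AD or the 15-year horizon.
  Optional independent exponential censoring (`followup_median`)
  reproduces the short, right-skewed follow-up of observational cohorts
  (median ≈ 2 y, IQR ≈ 1–4 y) while always keeping two visits; optional
  informative dropout ties the censoring hazard to the first marker score
  (emulating the observation that shorter follow-up accompanies worse
  impairment). Both are off by default: the default design observes
  subjects to the horizon, which is the regime in which the bundled
  recovery studies are informative.
* **Markers.** The 11 scales share a 4-factor latent structure with
  variance split 72.47/18.31/6/3.22% (the leading shares on the scale
  reported for the motivating cohort), built from two smooth orthonormal
  basis functions per marker with a fixed random orthonormal loading
  matrix, observation noise sd 0.5 and 10% missingness. Baseline
  covariate distributions are generic (age ≈ N(73, 7²), ~75% married,
  ~45% ε4 carriers, education ≈ 16±2.7 y) — the source cohort's exact
  distributions are not published precisely enough to match, and nothing
  downstream depends on them.
* **Regions.** Two smooth subject-level and two visit-level eigenfunctions
  over the 116-point domain with eigenvalue masses set by the target
  variance share ρ; mean profile near 100/116 % per region; noise
  sd 0.02.
* **Sparse functional draws.** `simulate_sparse_functional` places 5–12
  observations per subject uniformly on [0, 15] — intermittent attendance
  of a 6-monthly-to-annual schedule. This is the design of the FPCA
  recovery studies; with 3–8 observations per subject even the oracle
  PACE estimator (true eigensystem supplied) cannot reach a 0.9 score
  correlation, so recovery targets are only meaningful from about 5
  observations up.
* **Reproducibility.** All randomness flows through numpy's PCG64
  `default_rng`; a fixed seed reproduces cohorts bit for bit across runs.

## 7. Validation studies and their sizes

The test suite and `scripts/acceptance.py` run the same studies:
published-table percentage arithmetic (exact); matrix exponential vs ODE
oracle (1e-8) and the two-state closed form; intensity recovery and MVN
bootstrap coverage on 20 cohorts of n=1000 (each intensity within 20% and
covered by its 95% CI in ≥90% of replicates, B=500); score-effect
recovery β=0.5 on MCI→AD with ~95% CI coverage over 30 cohorts of n=400;
LRT null calibration over 50 cohorts of n=250 (KS uniformity);
FPCA recovery at n=500 over 5 replicates (eigenvalues within 15%,
mean eigenfunction angle <10°, PACE correlation >0.9); multilevel
variance share within ±0.05 at n=300×4 visits for ρ ∈ {0, 0.6, 1} with
fast/traditional eigenvalue agreement within 5%; and observed-vs-expected
self-consistency within 3 percentage points at n=2000. These sizes keep
the full suite within a few minutes on one CPU while leaving comfortable
margins on every tolerance.

Passing them shows the estimators recover the generating process under
the model's own assumptions. It does not establish robustness to
misspecification real cohorts exhibit: practice effects and floor/ceiling
effects in the scales, diagnosis misclassification, informative
assessment and dropout, non-Markov dependence on time since entry, or
scanner effects in the imaging stream.

## 8. Known limitations

* Time-inhomogeneous intensities, hidden-Markov misclassification and
  joint longitudinal–survival modelling are out of scope.
* The LRT for β-coefficients of estimated (generated) scores ignores the
  first-stage estimation error of the scores, as two-stage designs
  generally do.
* The disattenuation in MVFPCA assumes independent measurement errors
  across markers; duplicated or strongly error-correlated markers
  overcorrect (use `attenuation_correction=False` there).
* `pipeline.run_pipeline` caches score extraction within a run (shared
  across the model suite) but not across processes.
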
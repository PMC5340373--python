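# Methods

## Model

One row of the normative database is a single test score. For test
m ∈ {1..p}, participant j, study k:

    y_mjk = γ_m0 + γ_m1 age_jk + γ_m2 gender_jk + γ_m3 education_jk
            + ν_mk + ε_mjk

* Fixed effects: a per-test intercept and per-test covariate slopes. Slopes
  are common to all studies (no random slopes — an explicit non-goal).
* ε_jk = (ε_1jk … ε_pjk)' ~ N(0, Σ_w): the within-study residual
  covariance is completely unrestricted (p(p+1)/2 parameters) and equal
  across studies.
* ν_k ~ N(0, diag(σ²_b)): per-test study intercept errors, independent
  across tests (between-study covariances fixed at 0 — "average"
  participants are not expected to covary at the study level).

Covariates are centered on their participant-level means (each participant
counted once, not once per score row, so participants who completed more
tests do not dominate); gender is contrast coded ±1. A patient's covariates
are centered with the *norm group's* constants, never on their own, because
the predicted profile must live on the norm scale.

Missing scores arise because a study never administered a test (missing by
design) and are simply absent rows; the likelihood uses whatever each
participant observed (FIML). Identification of the unrestricted Σ_w
requires every pair of tests to co-occur in at least one study;
`pair_coverage` checks this and fitting refuses otherwise, naming the
uncovered pair. Rows with missing covariates are deleted listwise and
logged (covariate imputation is out of scope).

## Estimation

The per-study likelihood couples participants through the shared ν_k: two
participants' scores on the same test m covary by σ²_b,m. When all
participants of a study observed the same subset S (true for
missing-by-design data), the study covariance
I_n ⊗ Σ_w[S,S] + J_n ⊗ diag(σ²_b)[S] splits into n−1 orthogonal contrast
blocks with covariance V1 = Σ_w[S,S] and one mean block with
Vn = V1 + n·diag(σ²_b)[S] (a Helmert-style decomposition). The likelihood
then depends on the data only through per-study cross-product matrices;
those are additive across studies sharing (S, n), and the surviving
per-pattern computations are batched through 3-D LAPACK calls. One
likelihood evaluation therefore costs O(#patterns · p³) regardless of the
number of participants, and a fit at the default scale (15 000 scores)
takes ~0.05–0.1 s. Studies whose participants observed *different* subsets
(participant-level ignorable missingness) fall back to dense assembly of
the full study covariance; this path is exercised by oracle tests against
a brute-force multivariate-normal density.

Optimization is over variance parameters only: for fixed (Σ_w, σ²_b) the
fixed effects are the exact GLS solution, and by the envelope theorem the
profiled gradient needs no γ-derivatives. Parameterization is log-Cholesky
for Σ_w (always positive definite) and log for each σ²_b (non-negative;
the zero boundary is approached as the log parameter floors at −18, and
estimates below 1e-6 are reported as exactly 0). L-BFGS-B with analytic
gradients runs until the relative log-likelihood change is below 1e-8
(configurable), with up to 3 restarts from jittered starts on failure;
non-convergence is reported, never silently accepted. Starting values are
method-of-moments: per-test least squares ignoring nesting for γ,
pairwise-complete within-study-centered residual covariances
(eigenvalue-floored to positive definiteness) for Σ_w, and the
between-study variance of per-study mean residuals (floored at 1e-4) for
σ²_b.

REML is deliberately not offered — the method is defined with FIML. A
consequence documented by the acceptance suite: ML shrinks variance
components by O(1/K), so with K = 30 studies the between-study variance is
recovered ≈ 5% low on average while every other parameter is unbiased. On
single-test data the fit reproduces statsmodels MixedLM (ML) to five
decimals (a unit test), so this is a property of maximum likelihood, not
of the implementation.

Fixed-effect standard errors come from the GLS information matrix at the
optimum; variance-parameter uncertainty is not reported (it is nuisance
for the normative comparison).

## The comparison

* Combined covariance C = Σ̂_w + diag(σ̂²_b): the predictive covariance of
  a new participant from a new, unobserved study. When the model is fitted
  with between-study variance disabled, C = Σ̂_w (the "neglected" variant
  used for the calibration contrast). Boundary σ̂²_b = 0 simply adds 0.
* Predicted profile ŷ = Γ[1, age, gender, education]'. Covariates outside
  the norm group's observed range trigger an extrapolation warning, not an
  error.
* T² = [n/(n+1)]·[(n−p)/((n−1)p)]·(ŷ−x)'C⁻¹(ŷ−x), referred to F(p, df₂)
  with df₂ = N_obs − (K + q + 1), q = p·(1 + #covariates) counting fixed
  effects only (variance components are absorbed by the "+1"; this df
  convention is adopted from standard multilevel software). n stays the
  total participant count in the scaling constants — for n > 100 the
  choice is immaterial; `t2_norm(..., df_scaling="adjusted")` exposes the
  alternative that substitutes df₂ into the classical constants,
  agreeing to O(1/n).
* One-sided rule: flag the patient iff Σ_m (x_m − ŷ_m)/√C_mm < 0 and the
  two-sided p ≤ 0.10. Standardization uses √diag(C); "lower is worse" is
  assumed after any recoding of inverted scales (the caller's
  responsibility). Under the null this targets a 5% rate.
* Univariate comparisons: t_m = (x_m − ŷ_m)/√(C_mm(n+1)/n) against a t
  distribution with the same adjusted df (the df choice is ours; it is
  inconsequential at these df), one-sided at α = 0.05 uncorrected and
  α/p Bonferroni.
* The patient must have scores on all modeled tests; the intended workflow
  for incomplete patients is to refit the model to the completed subset
  (the errors say so).

## Synthetic data

`SimulationConfig` defaults *are* the stated simulation world: p = 10
tests, K = 30 studies × 50 participants, intercepts 20, effects
(−0.125/yr, 0.5, 1.25), within variance 25 with equicorrelation 0.4,
between variance 5 (ICC 0.167; 17 for the ICC-0.4 follow-up), deviations
of 2 total SDs (2√30 ≈ 10.95) subtracted from the first n_deviations
tests, 1000 replications.

Unstated details were fixed once: covariate distributions are
age ~ N(0, 15²) years, gender ±1 equiprobable, education ~ N(0, 1.5²)
(under a correctly specified model the null rejection rate is insensitive
to this choice; the scales make covariate contributions comparable to the
fixed effects). Patients draw fresh covariates by default
(`patient_covariates="average"` fixes them at zero). Unbalanced conditions
draw study sizes from N(mean, sd), rounded, floored at 5. Each replicate's
patient is drawn from a fresh, unobserved study, so their residual
covariance is Σ_w + diag(σ²_b).

The block-missingness generator assigns each study exactly
b = p·(1−fraction) tests by a deterministic greedy pair-covering rule
(seed each study with the least-covered pair, grow by the test adding the
most uncovered pairs). It guarantees exact overall missing fraction and
full pair coverage, and raises with the deficit when coverage is
infeasible. The 5-test condition uses 60% missing (b = 2) because 70% of 5
is not whole.

What the generator does **not** emulate: non-normal scores (skew, floors
and ceilings common in real tests), non-ignorable missingness, test-score
harmonization problems across studies, and covariate measurement error. A
green calibration test therefore establishes correctness of the machinery
under the model's own assumptions, not robustness to their violation.

Replicate seeds derive from the master seed by counter
(`SeedSequence(seed, spawn_key=(replicate,))`), so results are
bit-identical across runs and across `n_jobs` settings. Non-converged
replicates are excluded and counted (a rerun option exists); a condition
with >10% failures is flagged unreliable.

## Known behaviors and limitations

* Sensitivity is not strictly monotone in the number of deviating tests: a
  profile deviating on ~all tests points along the high-variance
  equicorrelation direction of C, so 9 deviations are slightly *harder* to
  detect multivariately than 5 (truth-parameter oracle: 0.85 → 0.80). The
  acceptance suite pins the empirical curve to that oracle.
* With many tests relative to studies (20 tests, 70% missing) some
  covariances rest on a single study and false positive rates inflate —
  reproduced, not fixed; restricting Σ_w (e.g., factor structure) is out
  of scope.
* The between-study variance carries the O(1/K) ML shrinkage discussed
  above.
* Education is treated as a generic continuous covariate; its raw scale is
  the caller's concern.
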
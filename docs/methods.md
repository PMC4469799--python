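# Methods

## Model and estimands

For individual *i* with genotypes G_ij ∈ {0,1,2} at J uncorrelated
bi-allelic variants, an unobserved confounder U_i and independent unit-normal
errors, the structural model is

    X_i = Σ_j γ_j G_ij + U_i + ε_Xi
    Y_i = Σ_j α_j G_ij + β X_i + U_i + ε_Yi

β is the causal effect of the exposure X on the outcome Y; γ_j is variant
*j*'s effect on the exposure; α_j is its *direct* (pleiotropic) effect on the
outcome.  The reduced-form association of variant *j* with the outcome is
Γ_j = α_j + β γ_j, so the per-variant ratio estimand is
Γ_j/γ_j = β + α_j/γ_j.  The IVW estimand equals
β + Σ γ_j σ_Yj⁻² α_j / Σ γ_j² σ_Yj⁻² (implemented as
`theoretical_bias`): valid instruments (α ≡ 0) or exactly cancelling
pleiotropy make it β.  MR-Egger's slope estimand is β whenever
cov(α, γ) = 0 across variants — the InSIDE condition — because the free
intercept absorbs the mean direct effect.

Taking the confounder's coefficients on X and Y as equal (both 1) is a
convenience; the estimators never see U and nothing downstream depends on it.

## Inference conventions

- Weights in both regressions are σ_Yj⁻², the inverse variances of the
  gene–outcome associations only (first-order weights).  The ratio SE is the
  matching first-order delta approximation σ_Yj/|γ̂_j|; second-order weights
  that propagate uncertainty in γ̂_j are out of scope.
- `se_model="regression-output"` (default): SEs include the estimated
  residual scale of the weighted fit, and tests/CIs use a t reference on
  J−1 (IVW) or J−2 (MR-Egger) degrees of freedom.  This multiplicative
  over-dispersion model is what makes the simulated type-I error of the IVW
  test come out at the nominal level here.  `se_model="fixed"` gives the
  known-variance (fixed-effect meta-analysis) convention with a normal
  reference; point estimates are identical.
- Confidence intervals use t quantiles at the estimate's df, consistent with
  the regression-output model.  Whether published applied analyses used t or
  normal quantiles is generally unstated; with J ≥ 29 the difference is
  small.
- Cochran's Q is computed against the IVW pooled estimate with the same
  first-order weights and referred to χ²(J−1): Q equals the weighted residual
  sum of squares of the through-origin regression.
- Orientation: variants with γ̂_j < 0 have (γ̂_j, Γ̂_j) sign-flipped and
  eaf → 1−eaf (allele recoding); SEs are untouched.  A variant with
  γ̂_j = 0 carries no orientation information and is left as-is with a
  warning (the fatal zero-denominator case is the ratio estimate, not
  orientation).  IVW, Q and the mean F statistic are invariant to per-variant
  recoding; MR-Egger is not, which is why it demands an oriented dataset.
- Exact-fit inputs (zero weighted residuals) produce zero SEs; p-values then
  degenerate to 0 (or 1 for a zero estimate) and CIs to a point, rather than
  raising.
- Estimates are kept at full precision throughout; rounding happens only in
  CLI display.

## Simulator defaults and calibration

Two cohorts of N individuals each are drawn independently (seed-split via
`numpy.random.SeedSequence.spawn` from one parent seed: one child stream for
the effect draw, one per cohort), the exposure associations estimated in the
first and the outcome associations in the second by closed-form univariate
least squares per variant.  Defaults:

| parameter | default | meaning |
|---|---|---|
| J (`n_variants`) | 25 | instruments per dataset |
| MAF law | U(0.1, 0.5) | per-variant allele frequency, Hardy–Weinberg genotypes |
| γ law | U(0.5, 1.5) × `gamma_scale` | instrument effects (exposure units/allele) |
| α law | 0 / U(−c, c) / U(0, c) | scenarios a / b / c,d |
| c (`pleiotropy_scale`) | 0.1 | direct-effect scale (outcome units/allele) |
| confounder path (d) | 2.5 α_j | per-variant effect on U, violating InSIDE |
| var(U), var(ε) | 1 | confounder and noise variances |

Scenario (d) is implemented as per-variant paths into the single shared
confounder U (one interpretation of "pleiotropy through a confounder"); the
induced effective direct effect of variant *j* on Y is α_j(1 + 2.5) while its
confounder path also inflates γ̂_j, correlating the two.

**Strength calibration.** `calibrate_strength` targets a mean per-variant F
statistic using the approximation E[F_j] ≈ 1 + N γ_j² v_j / r_j with
genotype variance v_j = 2p_j(1−p_j) and residual exposure variance
r_j = Σ_{k≠j} γ_k² v_k + 2, averaged over the parameter laws; the
`gamma_scale` root is found by Brent's method and verified by a pilot
simulation (±5%).  A single scale (≈1.345) then yields mean F ≈ 10.4, 19.8,
29.2, 38.6 at N = 250…1000 — the excess mean F is proportional to N at
fixed γ — so one calibration covers a whole sample-size sweep.

**Pleiotropy scale.** c = 0.1 was fixed from the asymptotic bias formula:
under scenario (c), E[Bias] = E[α]·E[γv]/E[γ²v] ≈ (c/2)/(1.345·1.083) ≈
0.034 in outcome units, a bias comparable to the IVW SE at N ≈ 250 and hence
clearly visible without saturating the tests.  At these settings the desk
runs show IVW null rejection rising from ≈0.33 (N=250) to ≈0.83 (N=1000)
under (c) while MR-Egger's stays at ≈0.05, and scenario (d) biases IVW about
three times more than (c).

**What the generator does not emulate.** Linkage disequilibrium between
instruments, binary outcomes/logistic reduced forms, sample overlap (and
hence winner's-curse selection), non-linear effects, and effect
heterogeneity.  Passing tests therefore certify the estimators' behaviour
under the linear two-sample model with independent variants, not robustness
to those real-data features.

## Study driver

`run_cell` simulates n_reps replicate dataset pairs, orients each, fits IVW
and MR-Egger, and records mean estimates, mean SEs, rejection rates of the
causal null at the nominal level (default 5%, same t reference as the
estimators) and of the MR-Egger intercept test.  Degenerate replicates (e.g.
a monomorphic variant at tiny N) are redrawn from a fresh sub-seed, counted
in `n_retries`, and abandoned after 10 attempts.  `run_grid` derives each
cell's seed as a SHA-256 hash of (master seed, scenario, β, N, J), so grids
are reproducible and order-independent.  The full published-scale grid is
10 000 replicates per cell; the bundled tests and the acceptance script use
2000 and 5000 replicates respectively, sized to give Monte Carlo standard
errors of ~0.005 and ~0.003 on a 5% rejection rate.

## Plots

The scatter plot shows Γ̂ against γ̂ with the IVW line through the origin
(red), the MR-Egger line with its intercept (blue) and optionally the true
slope (dotted).  The funnel plot puts the per-variant ratio estimate on the
horizontal axis and instrument strength on the vertical axis — raw γ̂_j, or
γ̂_j√(2p_j(1−p_j)) with `maf_correction` (under Hardy–Weinberg this is
proportional to the σ_Yj⁻² weighting the regressions already use).  Note the
axis convention: classic meta-analysis funnels plot the *estimate*
horizontally against precision too, but here the vertical axis is instrument
strength, not pooled-estimate precision.  Plots never recompute statistics;
coordinates and reference lines are taken verbatim from the estimator
outputs.

## Known limitations

- No universally validated SE for the MR-Egger slope when the causal effect
  is non-zero; CIs far from the null warrant caution.  Bootstrap CIs are
  deliberately not offered.
- Correlated instruments (generalized weighted regression), multivariable
  MR, allele-score and median/lasso/k-class estimators are out of scope.
- The file reader performs no allele harmonization against a reference
  (strand flips, rsID matching); inputs are assumed pre-harmonized, and
  orientation handles only the sign convention.
- Exact published simulation parameter sets are not always available;
  scale-dependent quantities (absolute bias magnitudes) depend on c and the
  γ law, whereas calibration-robust quantities (type-I error, null
  unbiasedness, the qualitative scenario contrasts) do not.
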
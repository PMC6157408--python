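# Methods

## Model

A four-member family (roles M, F, T, S) provides 12 ordered dyadic
measurements, actor-major order MF, MT, MS, FM, FT, FS, TM, TF, TS, SM,
SF, ST.  The social relations model treats each as

    X_ij = Fam + Act_i + Par_j + Rel_ij + eps_ij,

with one indicator per dyad, so `Rel_ij` is absorbed into the residual.
As a confirmatory factor model: 9 latent effects in the order
(fam, act_M..act_S, par_M..par_S), a fixed 12 x 9 unit-loading matrix Λ
(row (i,j) has ones at fam, act_i, par_j), factor covariance Ψ whose only
off-diagonal entries are the four same-role actor–partner covariances
(generalized reciprocity), and residual covariance Θ whose only
off-diagonal entries are the six `eps_ij`–`eps_ji` covariances (dyadic
reciprocity).  Σ = ΛΨΛ' + Θ.

Λ has rank 7: its null space is spanned by
(−1,1,1,1,1,0,0,0,0) and (−1,0,0,0,0,1,1,1,1) — the family column equals
the sum of the actor columns and of the partner columns.  This drives
everything unusual below.

The mean structure carries 21 effect means reduced to 12 free parameters
by zero-sum constraints: actor means sum to zero, partner means sum to
zero, and relationship means are doubly centered (each actor's three and
each partner's three sum to zero; 7 independent constraints).  The map
between a 12-vector of dyadic means and the constrained components is a
bijection; the closed form at family size n = 4 is

    fam   = grand mean of the 12 cells,
    act_i = (9/8) rowmean_i + (3/8) colmean_i − (3/2) grand,
    par_j = (9/8) colmean_j + (3/8) rowmean_j − (3/2) grand,

with relationship components the doubly-centered remainder.  Applied to
a single family's raw table these same weights are the classical
"ANOVA scores".  Factors are kept centered in Ψ; all means live in the
mean structure, so measurement intercepts are zero and the score systems
operate on `x − μ`.

Free parameters of the measurement model: 13 in Ψ (9 variances + 4
reciprocities), 18 in Θ (12 variances + 6 reciprocities), 12 means — 43.

## Factor scores

With estimated (Λ, Ψ, Θ, μ), per family:

* **Regression** (Thurstone–Thomson / empirical Bayes):
  `η̂ = Ψ Λ' Σ⁻¹ (x − μ)`, numerically identical to
  `(Ψ⁻¹ + Λ'Θ⁻¹Λ)⁻¹ Λ'Θ⁻¹ (x − μ)` by the Woodbury identity.
* **Regression, casewise (FIML)**: the same second form with Λ, Θ, μ
  restricted to the family's observed indicators.  Valid under MAR given
  the observed dyads.  A family with nothing observed shrinks fully to
  the factor mean (score 0).
* **Bartlett**: `(Λ'Θ⁻¹Λ)⁻¹ Λ'Θ⁻¹ (x − μ)`, or the GLS weighting with
  Σ⁻¹, which coincides when the 9 x 9 system is invertible.  For the SRM
  it is not (rank 7), so these variants raise an explicit rank error;
  the pseudo-inverse variant `(Λ'Θ⁻¹Λ)⁺ Λ'Θ⁻¹ (x − μ)` is always
  defined, and its casewise version handles missing data.  A family with
  nothing observed has no Bartlett score (there is no prior to shrink
  to); the row is left missing.
* **ANOVA**: the two-way weights above on the family's own table; any
  missing dyad leaves all nine scores missing.

Scores are reported as deviations from the factor means (`add_means=True`
adds the estimated SRM means back).  Pseudo-inverse rank decisions use a
relative singular-value cutoff of 1e-10: the rank deficit is structural,
and a tight relative tolerance prevents sampling noise in an estimated Θ̂
from flipping the detected rank.

### Bias geometry

`FSC_B Λ = P = (Λ'Θ⁻¹Λ)⁺ Λ'Θ⁻¹Λ` is the orthogonal projector onto the
row space of Λ: symmetric, idempotent, rank 7, invariant to any positive
definite Θ, with 3-decimal entries 0.667 (family diagonal), 0.167
(family cross), 0.792 / −0.208 (within actor and partner blocks), 0.042
(actor–partner).  Bartlett scores as regression outcomes therefore
estimate `P Γ`; when the actor and partner coefficient blocks each sum
to zero columnwise, the family row of `P Γ` is exactly 2/3 of the true
family row (0.667·γ + 0.167·0).

For regression scores as predictors the unbiasedness identity
`(FSC_R Σ FSC_R')⁻¹ FSC_R Λ Ψ = I` holds globally in the full-rank
case.  Under rank deficiency `var(η̂) = ΨΛ'Σ⁻¹ΛΨ` has range
`Ψ · rowspace(Λ)`, and the identity holds exactly on that subspace —
note this is *not* the range of P itself unless Ψ maps the row space to
itself (it does not under the default generating values, where partner
and family variances differ).  `regression_identity_check` therefore
projects onto range(ΨΛ') and reports the maximal residual; perturbing
the loading matrix used by the scores breaks the identity, which the
check exposes.  The per-role regressions actually run in the pipelines
(an outcome on that role's family/actor/partner scores) are exactly
unbiased at the population level under the defaults; this was verified
directly from the population covariance algebra.

## Estimation

All fits maximize a structured multivariate-normal likelihood.  Families
are grouped by missing-data pattern; each pattern contributes through
sufficient statistics (the moment matrix of observed indicators, fixed
regressors and a constant), so one likelihood evaluation costs
O(#patterns x dim³) independent of sample size.  Gradients are analytic:
Σ is linear in the Ψ/Θ parameters (and quadratic in the structural
loadings of the joint SEM), so each derivative is a sparse contraction
of the per-pattern gradient matrix.

* `fit_srm_ml` — complete families only (incomplete ones logged and
  excluded); `fit_srm_fiml` — casewise over all patterns; they coincide
  on complete data.
* `fit_joint_sem`, predictor direction — the role-specific outcomes join
  the observed vector; each y_r loads on (fam, act_r, par_r) with free
  intercept and residual variance (63 parameters with all four roles).
* `fit_joint_sem`, outcome direction — a MIMIC-style model: the nine
  effects are regressed on external predictors z_1..z_K treated as fixed
  regressors; per-column zero-sum constraints on the actor and partner
  blocks are enforced by parameterizing three free rows per block and
  deriving the fourth (43 + 7K parameters).  Standard errors for the
  derived rows come from the delta method.

Numerical choices: variances are optimized unconstrained, so
Heywood-type solutions can occur and are *flagged*, not prevented — a
fit counts as converged only if the optimizer succeeded (L-BFGS-B,
projected-gradient tolerance 1e-6) **and** the fitted Σ is positive
definite (smallest eigenvalue > 1e-10).  Outside the PD region a soft
eigenvalue barrier steers the search back.  Starting values are
moment-based: ANOVA-score variances and residual moments when at least
10 complete families exist, pooled-variance heuristics otherwise; the
joint SEM can warm-start from a measurement-only fit.  The
parameter covariance is the inverse observed information, computed by
central differences of the analytic gradient at the optimum.
Non-converged fits are returned for inspection but refuse Wald tests,
and the simulation harness excludes them from summaries while counting
them.

## Factor-score regression

Step 1 fits the measurement model (ML for complete-data scores, FIML for
casewise scores), step 2 computes scores, step 3 runs OLS — either an
outcome on a role's (fam, act_r, par_r) scores or each of the nine
scores on the predictors.  Families with missing scores are dropped
listwise in step 3 with a logged count; fewer than five usable families
is an error.  Naive SEs are classical homoskedastic OLS SEs — they are
exactly the quantity known to be optimistic, because the scores are
estimated; the family bootstrap (default B = 500, resampling families
with replacement and repeating all three steps, redrawing non-converged
resamples up to 3B attempts) provides the honest alternative.  For truly
null coefficients the naive SEs are essentially calibrated; for nonzero
coefficients on poorly measured effects (partner effects in particular)
they can understate the sampling variability by a factor of two.

## Synthetic data

The generator emulates the study conditions the estimators are meant
for; its defaults are the standard generating values throughout:

* variance components — family 1, actor 1 (all roles), partner 0.5,
  relationship+error 1.5 (all dyads); generalized reciprocities of
  magnitude 0.05 (+ for M and T, − for F and S; the role assignment of
  the signs is a package convention, overridable); dyadic reciprocities
  0.02.  Every dyadic variance is then 4.0 with shares
  (0.25, 0.25, 0.125, 0.375).
* predictor condition — role-specific outcomes
  `y_r = b_fam·Fam + b_act·Act_r + b_par·Par_r + N(0, 1)`.  The
  structural coefficients are configuration; the defaults are
  F (0.3, 0, 0.2), T (0.2, 0.3, 0), S (0, 0.2, 0.3) and role M fully
  null.  The null role matters: a zero coefficient inside a role with
  nonzero effects is *not* a clean null for the biased score methods
  (their subset-regression estimands mix the role's coefficients), so
  type-I behaviour — which should be correct for every method — is
  assessed on role M, where all methods' estimands are exactly zero.
* outcome condition — z_1..z_3 i.i.d. standard normal and mutually
  independent by convention; effects
  `η = Γz + ζ` with the variance components above as disturbance
  covariance.  Γ's family row is (0.021, −0.005, −0.094); partner rows
  are zero; actor rows are package defaults chosen to satisfy the
  zero-sum constraint: M (0.10, 0.05, −0.02), F (−0.05, 0.02, 0.06),
  T (0.02, −0.04, −0.01), S derived.
* missingness — independent per-cell deletion inside the stratum where a
  conditioning variable falls below its empirical first quartile
  (numpy's linear-interpolation quantile).  Mechanisms: predictor
  condition, dyad-dependent (X_TM, X_TF at 25% given X_TS < Q1) and
  outcome-dependent (X_TM, X_TF, X_TS at 25% given y_T < Q1); outcome
  condition, dyad-dependent (X_TM, X_TF, X_TS, X_FM, X_FT, X_FS at 40%
  given X_SM < Q1) and predictor-dependent (the same six given z_1 < Q1
  plus X_TM, X_TF, X_TS, X_MF, X_MT, X_MS at 40% given z_2 < Q1).
  "Missing rate" is reported as the fraction of families with at least
  one missing dyad — the definition under which the closed forms
  0.25·(1 − 0.6⁶) ≈ 23.8% and 0.25·(1 − 0.75³) ≈ 14.45% hold.

What the generator does **not** emulate about real family data:
responses are continuous multivariate normal (real rating parcels are
bounded, discrete-ish and often skewed), families are i.i.d. with a
fixed known role structure, missingness follows the stated mechanisms
exactly, and there is no longitudinal dependence.  Passing tests
therefore certify the estimators' behaviour under the model's own
assumptions, not robustness to violations of them.

## Monte-Carlo harness

Per replicate: generate, delete, then per method fit/score/regress
(SEM refits jointly; FSR methods share one measurement fit per
replicate).  Any failure counts as non-convergence for that method.
Summaries per method x coefficient over converged replicates:

* bias z = (median − truth) / (1.2533·SD/√R), the asymptotic SE of the
  median; |z| > 1.96 flags bias;
* coverage = share of replicates whose Wald 95% CI contains the truth;
* MAD = median |estimate − truth|;
* convergence rate and mean family-level missing rate;
* mean and SE of the mean are also reported (used when comparing
  Bartlett outcome coefficients against `P Γ`).

Cells with fewer than 30 converged replicates are flagged, not
summarized.  A single master seed spawns independent per-replicate
streams, so identical config + seed reproduces summaries bit-for-bit.

Problem sizes used by the shipped checks: the comparative studies run
200 replicates of n = 500 families (enough that the median-bias SE is
~0.004 and a coverage of 0.95 is estimated to ±0.015); missing-rate
targets average 20 replicates of n = 2,000; FIML recovery uses one
dataset of n = 5,000; moment checks use up to 200,000 draws.

## Known limitations

* The simulated mean Bartlett outcome coefficients sit close to, but not
  exactly on, the analytic `P Γ` values (e.g. −0.060 simulated vs
  −0.063 analytic for the third predictor at n = 500) because step-1
  estimation error in Θ̂ and μ̂ perturbs the realized score coefficients;
  the package reports both quantities rather than forcing agreement.
* Non-convergence rates of the joint SEM depend on the optimizer,
  starting values and sample size; they are diagnostics, not calibrated
  quantities.
* Bartlett casewise scores have pattern-dependent effective rank (7 for
  complete data, lower when informative indicators are gone); score
  components outside the identified subspace of a pattern are
  pseudo-inverse minimum-norm solutions, not estimates.
* Out of scope by design: multiple indicators per dyad (no separation of
  relationship from error), variable family size or role-free groups,
  effect-coded loadings, REML and Bayesian estimation, Croon /
  Hoshino–Bentler corrections, and global fit indices.
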
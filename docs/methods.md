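# Methods

## Model representation

Models are stored in reticular-action-model (RAM) form (`lcsm.model.PathModel`):
a directed-edge matrix `A` (regressions, loadings), a symmetric
undirected-edge matrix `S` (variances, covariances), and a mean vector
`M`, over a variable ordering with observed variables first. Cells hold
either fixed numbers or free-parameter labels; cells sharing a label are
equality-constrained. Implied moments are `μ = Fm B M` and
`Σ = Fm B S Bᵀ Fmᵀ` with `B = (I − A)⁻¹` and `Fm` the observed-row
filter. Degrees of freedom are counted as `p(p+1)/2 + p` observed
moments minus distinct labels; all structural edits (freeing a cell off
an equality constraint, fixing a label) are pure functions that return a
new model.

### Identification and structure choices

- First indicator per occasion: loading fixed 1, intercept fixed 0;
  latent occasion means are carried by the intercept/slope structure.
- Change-score means and residual variances fixed 0 except under the
  retest option (free mean, optionally free variance, of the first
  change score).
- Correlated residuals of the same indicator span **all** occasion
  pairs (6 pairs × 4 indicators in the speed model). Lag-limited
  variants are inconsistent with the model's moment-minus-parameter
  count, which the symbolic-counter tests pin down exactly.
- All exogenous observed covariates — time-invariant (age, education,
  gender) **and** time-varying (head motion per occasion) — form one
  saturated stochastic block: free means and a fully free covariance
  matrix among them. This is required for FIML to tolerate incomplete
  covariates and is what the df accounting implies.
- Single-indicator tract models constrain the head-motion regression to
  one coefficient over occasions while leaving residual variances free
  per occasion. The mirrored convention (free motion paths,
  equality-constrained residuals) yields the same df; the single
  time-varying-covariate effect is the conventional reading and is the
  package default.
- The proportional-change extension (`β · η_{t-1} → Δη_t`) exists as a
  builder flag and defaults off; with it the model is no longer
  equivalent to a linear growth curve.
- Time grid in years with a phantom latent occasion at year 3 and all
  slope loadings 1, so `μ_S` is annual change.

## Estimation

FIML over missingness patterns: rows are grouped by pattern; each
pattern contributes the multivariate-normal log-density of its observed
subvector under the marginalized implied moments. Identical to row-wise
evaluation, cached per pattern.

The analytic gradient aggregates the per-pattern derivatives with
respect to (Σ, μ) into one observed-block matrix, after which each
parameter's derivative is a rank-1/rank-2 inner product — a few vector
operations per cell. Optimization is L-BFGS-B (warm start, memory 30)
followed by Newton polish with a ridge-regularized forward-difference
Hessian until the gradient max-norm falls below 1e-5 (up to 50 steps;
line-search backtracking). Starting values are deterministic
moment-based recipes attached by the builders (sample means/covariances
for the exogenous block, half the sample variance for residuals, OLS
slope of occasion means for `μ_S`, zeros for regressions and couplings),
so every fit is exactly reproducible.

Standard errors come from the inverse observed information (central
finite differences of the analytic gradient); Wald p-values are
two-sided normal. Modification indices are one-df efficient score
statistics: the candidate cell is freed at its current value, the
bordered information matrix assembled from the stored Hessian plus one
finite-difference column, and `gᵀ I⁻¹ g` reported; singular borders are
skipped with a note.

Non-positive-definite implied covariances on a pattern yield a penalized
objective (recorded, never silent). Negative variance estimates
(Heywood cases) are flagged; with the fix option the offending variances
are pinned to zero and the model refit once. Nested comparison chains
(retest contrast, coupling series) are fit *without* the boundary fix,
because a mid-chain refit changes df and breaks nesting; flags are
logged instead.

The saturated model is fit by EM over missingness patterns (tolerance
1e-9 relative on the log-likelihood); the independence model factorizes
per variable and is closed-form. χ² = 2(llₛₐₜ − llₘ); numerically
negative differences are floored at zero with a warning.

## Fit evaluation and selection

- CFI uses the noncentrality form with floors at zero.
- RMSEA = √(max(0, (χ² − df)/(df·n))) with n the number of rows entering
  the FIML objective; the 90% CI inverts the noncentral-χ² CDF
  (Brent root-finding on the noncentrality parameter).
- Sample-size-adjusted BIC = −2·ll + k·ln((n+2)/24) (Sclove/Yang
  effective sample size). Printed BIC levels depend on the raw data and
  are not reproducible from summaries; only orderings are tested.
- Nested models: plain ML χ² difference at α = 0.01.
- Invariance steps: accept the more constrained model iff the CFI drop
  is ≤ 0.01 (with a 1e-12 epsilon so exact-boundary drops accept).
  Note the CFI is not mathematically monotone along
  configural → weak → strong: when Δχ² < Δdf the noncentrality estimate
  falls and the CFI rises; the decision rule uses the signed drop.
- Coupling-model selection: among coupling models significant against
  baseline at α = 0.01, lowest adjusted BIC wins; otherwise baseline.
  An override argument lets substantive considerations force a named
  model.

## Invariance cascade

Configural → weak → strong, each step decided by the ΔCFI rule; on
strong-MI rejection, intercepts are freed one indicator at a time —
highest modification index first, ties broken by earliest occasion then
indicator order — and freeing an indicator releases its intercepts at
every non-reference occasion at once (partial-strong). The reference
indicator's intercepts stay fixed throughout. The freeing budget
(`max_freed`) caps the cascade.

## Preprocessing

- MAD screening pools all occasions of a variable into one distribution;
  threshold median ± k·(c·MAD) with k = 3 and consistency constant
  c = 1.4826 by default (configurable to 1.0 — exact removal counts are
  data-dependent, so the constant is exposed rather than asserted).
  Cognitive scores are screened two-sided; head motion one-sided
  (upper), and a motion flag blanks that occasion's FA cells while
  keeping the row (speed data at the same occasion survive, as FIML
  requires).
- Hemispheric averaging: voxel-count-weighted mean of left/right
  homologous tracts; a missing side falls back to the other.
- Model scale: FA × 100 (avoids estimation artifacts from the three
  orders of magnitude between raw FA and speed scores), timing scores
  × (−1) so higher = better, age centered at 70, education centered at
  level 2, gender and head motion untouched.
- Selectivity index: (follow-up-sample baseline mean − full baseline
  mean)/baseline SD, read against the 0.20 weak-effect cut-off.

## Synthetic cohorts

The generator (`lcsm.simulate`) mirrors the analysis model: covariates
drawn from fixed distributions with closed-form moments (age ≈
N(70.8, 5.1²) centered, education a centered three-level discrete,
gender Bernoulli ~0.51, head motion lognormal with median 0.2 — right-
skewed so MAD screening has work to do); intercepts and slopes jointly
normal across domains given covariates; trajectories rolled on the
annual grid including the phantom year; lagged coupling contributions
added change-by-change; a retest bump (+2 raw units by default) on the
first speed change; indicators with exchangeable-correlation residuals
across occasions; head-motion contamination of FA indicators
(−2 per unit motion on the ×100 scale).

Missingness: monotone dropout matched to retained counts
(default 232→210→197→173, proportionally scaled for other n), weakly
age-dependent by default (MAR; log-odds 0.06 per year above the cohort
mean, toggleable to MCAR); element-wise MAR cell missingness whose rate
depends on observed baseline age; ~3% missing education. Tract presets
cover three regimes — declining (μ_S = −0.30, σ_S = 0.28), stable
(μ_S = 0), and zero-slope-variance (the boundary case) — as scenario
templates for the qualitative regimes such cohorts show, not estimates
of any dataset. `true_estimates` maps a truth manifest onto every free
label of the matching model, which is what the moment-matching and
recovery tests compare against.

What the generator does **not** emulate: floor/ceiling effects and
discreteness of test scores, non-normal residuals, occasion-spacing
jitter, scanner upgrades or site effects, and covariate-dependent
measurement error. Passing recovery tests therefore show that the
estimator is correct and calibrated *under the model's own assumptions*,
not that those assumptions hold in any particular cohort.

## Problem sizes in the test suite

Deterministic checks run at full published configuration (19-, 11- and
27-variable models). Stochastic checks use the cohort's n (230 with
attrition) at 30 simulate–fit replicates for the bivariate recovery and
type-I runs, 12 replicates for the χ²-calibration check, and single
seeded datasets for the cascade scenarios; Monte-Carlo standard errors
scale with the replicate count, so the bias tests remain calibrated at
this scale. The bias criterion is three Monte-Carlo SEs on the
preregistered structural parameters (couplings, slope means, retest,
slope variances, cross-domain covariances), a Bonferroni family-wise
bound across all ~115 free parameters, and a 1%-of-scale allowance
covering the deterministic (n−1)/n maximum-likelihood scaling bias of
moment parameters.

## Known limitations

- ML estimator only: no robust (Huber-White) corrections, no
  WLSMV/ordinal estimation, no multi-group models.
- The score-test modification indices use a numerically bordered
  information matrix; for near-unidentified candidates they are skipped
  rather than stabilized.
- EM for the saturated model can, in principle, terminate within its
  tolerance slightly below the optimum; χ² values are floored at zero
  and comparisons carry a 1e-4 slack in tests.
- The global 10-tract FA factor model is buildable and the pipeline
  evaluates it, but its published df could not be reconciled by any
  parameter accounting, so no structural target is asserted for it.
- Coupling lags are multiples of the annual grid; continuous-time
  extensions are out of scope.
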
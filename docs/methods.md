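# Methods

## Model

All variants are Bayesian regressions whose coefficients carry the LN-CASS
prior: a coefficient is the product of a slab scale τ, a U-shaped
logit-normal inclusion weight λ ∈ (0, 1), and a standard-normal latent z.
Writing sigm for the logistic sigmoid,

    β = τ λ z,    λ = sigm(μ_λ + σ_λ u),    z, u ~ N(0, 1).

With σ_λ large the marginal prior of β approaches the two-point
spike-and-slab mixture: with probability 1 − a (a = sigm(μ_λ)) the
coefficient sits in a spike of negligible width at 0, otherwise it is drawn
from the slab N(0, τ²). Unlike the discrete mixture the posterior is fully
continuous, so gradient-based MCMC applies, and each λ is read as an
approximate inclusion probability at its own level of the hierarchy.

**Likelihoods.** Gaussian: y_i ~ N(β₀ + X_i β, σ_ε²); binomial: logit
P(y_i = 1) = β₀ + X_i β. The intercept has a vague N(0, 10²) prior; the
gaussian noise scale has a half-normal(0, 5) prior, sampled on the log scale
with the Jacobian included. Both nuisance priors are package choices — vague
but proper.

**Grouped variant.** For a partition of predictors into groups g with
members j,

    β_gj = τ · λ_g · (z_g + λ_gj · w_gj),

with an independent logit-normal gate at each layer. λ_g → 0 excludes the
whole group; λ_gj → 0 collapses member j onto the shared group coefficient
τ λ_g z_g; both limits are exact, which is the property the algebra was
chosen for. The complexity ladder is therefore: no effect → shared group
effect → individual effects, with successive gates composing
multiplicatively.

**Hierarchical GAM (binomial only).** Each covariate (scaled to [0, 1])
enters through a linear column plus K hinge columns max(0, x − κ_k); default
K = 5 knots equally spaced at k/(K+1). The effect curve is

    f_i(x) = τ λ_i z_i x + Σ_k τ λ_i λ_i^nl w_ik max(0, x − κ_k),

so λ_i gates the covariate entirely and λ_i^nl gates all curvature at once:
no effect → linear effect → nonlinear effect. With K = 0 the model reduces
exactly to flat logistic regression. Hinges are the minimal piecewise-linear
basis that nests linearity exactly; knot count and placement are
configurable. Reported effect curves are raw basis combinations — no
smoothing.

## Hyperparameters

* **τ = 5** (slab sd). Appropriate for standardized predictors, where it is
  a vague prior on any plausible effect size.
* **a = 0.5** (prior inclusion probability, μ_λ = logit(a) = 0). Set a lower
  if most predictors are believed null; a is exactly the prior median of λ.
* **σ_λ = 10**. Controls the quality of the spike-and-slab approximation;
  results are insensitive to increases. At 50 the prior is numerically
  indistinguishable from the discrete mixture at the 0.05·τ resolution.

## Inference

Sampling is a self-contained No-U-Turn sampler (slice-sampling tree variant)
with dual-averaging step-size adaptation and windowed diagonal metric
estimation, operating on hand-derived analytic gradients (numba kernels,
validated against central finite differences at relative tolerance 1e-4).
Every latent is non-centred — conditionally standard normal — which keeps
the U-shaped posterior geometry tractable.

Defaults: 4 chains × (1000 warmup + 1000 kept draws), target acceptance
0.95, tree depth capped at 8. The high acceptance target keeps the step
size small enough to cross the spike necks reliably; the depth cap halves
cost on the flat plateaus this posterior produces, with no measurable
effect on recovery quality or split-R-hat in the regimes tested (tens to
low hundreds of latents; worst split-R-hat ≤ 1.08 across seeds on the
p = 20 study). A few
divergent transitions per chain are typical near the spike necks; medians
and inclusion means — the quantities reported — are insensitive to them,
but tail quantiles of λ should be treated with care. Chains are seeded
independently from one user seed; identical seeds reproduce runs
bit-for-bit. Initialization retries up to three reseeds if it lands in a
non-finite region.

Convergence is monitored with split-R-hat (each chain halved, classic
between/within ratio on the half-chains), computed for every latent and
every derived quantity; the CLI flags any value above 1.1 prominently.
Summaries are computed on per-draw derived quantities (map first, then
median/quantiles). Hard selection, when wanted, thresholds the absolute
posterior medians (`select_top_k`; ties break to the lower index).

## Numerical choices

* λ is clamped to [1e-12, 1 − 1e-12] before any logit/log, and logit-normal
  sampling clamps sigm-saturated draws into the open interval (saturation is
  routine at σ_λ = 50, where |η| > 37 rounds sigm to exactly 0/1).
* The log of the gaussian noise scale is clipped at ±40 inside the density;
  the clipped region is unreachable except on divergent trajectories.
* Standardization uses the n−1 denominator. Unit-interval scaling stores
  training min/max and clamps new data into [0, 1], counting clamps.
* The Wald screen fits each univariate logistic regression by Newton
  iteration with a unit ridge (a weak N(0, 1) prior on the log-odds scale):
  with a near-zero ridge, perfect separation drives the Wald SE up faster
  than the coefficient, inverting the intended ranking.
* AUC uses the Mann–Whitney convention (ties count ½), making the
  trapezoidal curve area identical to pairwise concordance probability.
* Logit-normal normalization is verified by adaptive quadrature on
  [1e-12, 1 − 1e-12] plus the analytic normal-CDF mass of the endpoint
  slivers; at σ = 50 roughly a quarter of the mass lies below x = 1e-13,
  beyond the reach of x-space quadrature in double precision.

## Synthetic study conditions

The grouped recovery study mirrors a three-setting design at n = 100
observations with p = 20, 70, 120 predictors (5×4, 10×7, 15×8 groups). The
design matrix is a unit Latin hypercube (one point per 1/n bin per column,
independent column permutations); the response is y = β₀ + Xβ + ε with
ε ~ N(0, 1) and β₀ = 1. Each setting contains one shared-coefficient group
(all members 2.0), one heterogeneous group (values from
3, 1.5, −2, 0.5, −1, 2.5, 0.75, −1.5), and all remaining groups exactly
zero — the three behaviours the grouped prior is designed to distinguish.
The coefficient fixtures live in one place (`synthetic.default_scenarios`)
and are deliberately editable.

The GAM scene has 10 uniform covariates on [0, 1]: a centred quadratic
effect 16(x−½)² − 4/3 on covariate 1, a linear effect 5(x−½) on covariate
2, and eight nulls, feeding a Bernoulli-logit response. Amplitudes were
chosen so that n = 150 observations identify the curvature without making
the task trivial (both effects have standard deviation near 1.2 on the
logit scale).

**What the generators do not emulate:** correlated or heavy-tailed designs,
measurement error in X, missing data (datasets with missing values are
rejected; impute upstream), model misspecification beyond the one-label
misgrouping probe, and real-data effect-size distributions. Passing the
recovery tests therefore demonstrates correctness of the machinery under
the stated conditions, not field performance on any particular dataset.

Routine test and study runs use the p = 20 setting (a single-CPU fit takes
about a minute); the p = 70 and p = 120 settings run through the same
driver (`run_simulation_study`, `lncass study --settings p70,p120`) and are
intended as occasional long runs.

## Cross-validation

`run_cv` supports repeated (optionally stratified) k-fold and
leave-one-out. Class-balanced LOOCV removes one randomly chosen
opposite-class observation from each training fold (fold-indexed seed) so
class proportions are identical across folds, removing the prevalence bias
of plain LOOCV scores. Repeated k-fold is stratified by class when
`class_balance` is set; whether to stratify is a package choice, documented
here. Preprocessing transforms store their training-fold constants in a
`TransformRecord` so they can be re-applied to held-out folds without
leakage; re-screening inside each fold is likewise the leakage-safe default
for the Wald screen.

## Known limitations

* MCMC cost grows quickly past a few hundred latents; no variational
  approximation is provided.
* The GAM variant is binomial-only (logit link); a gaussian GAM is rejected
  with an explicit error.
* OLS is the only built-in frequentist baseline, and only where p < n;
  penalized-likelihood competitors are external.
* Inclusion weights are approximate inclusion probabilities, not posterior
  model probabilities; layers are reported separately and never silently
  multiplied.
* Divergent transitions are counted and exposed in the per-chain
  diagnostics rather than eliminated; raise `target_accept` (at higher
  cost) if tail inference on λ matters.
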
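# lncass

Bayesian sparse regression with the **logit-normal continuous analogue of the
spike-and-slab (LN-CASS) prior** — flat, grouped and hierarchical-GAM
variants — with built-in NUTS sampling, convergence diagnostics, evaluation
metrics and a synthetic parameter-recovery study harness.

## Who this is for

Applied biostatisticians and computational biologists facing *p ≫ n*
regression problems — metabolite panels, gene-expression classifiers,
grouped immunological predictors — who want the interpretability of classical
(generalized) linear models together with principled Bayesian shrinkage and
approximate variable-selection probabilities, without the combinatorial cost
of the discrete spike-and-slab.

## The prior

The classical spike-and-slab places a point mass at zero (spike) and a
diffuse slab elsewhere, gated by a Bernoulli indicator; posterior exploration
then requires visiting 2^p model configurations. LN-CASS replaces the
Bernoulli indicator with a continuous, U-shaped **logit-normal** weight:

    β_j = τ · λ_j · z_j,       z_j ~ N(0, 1),
    λ_j = sigm(η_j),           η_j ~ N(μ_λ, σ_λ²),

so the joint posterior is fully continuous and gradient-based MCMC applies.
The three hyperparameters are interpretable:

| parameter | meaning | default |
|---|---|---|
| τ | slab standard deviation (for standardized predictors) | 5 |
| a = sigm(μ_λ) | prior inclusion probability; the prior **median** of λ | 0.5 |
| σ_λ | sharpness of the spike-and-slab approximation | 10 |

Because λ ∈ (0, 1) multiplies the coefficient, hierarchies of model
complexity are built by **multiplying successive logit-normal weights**:

* **grouped** (no effect → shared group effect → individual effects):
  `β_gj = τ · λ_g · (z_g + λ_gj · w_gj)` — the group gate λ_g removes whole
  groups, the member gate λ_gj releases member-specific deviations;
* **hierarchical GAM** (no effect → linear → nonlinear): per covariate, a
  linear term `τ·λ_i·z_i·x` plus hinge-basis terms `τ·λ_i·λ_i^nl·w_ik·max(0, x−κ_k)`
  with a logit link, so the nonlinearity gate λ_i^nl opens only when the data
  demand curvature.

## Worked example

```python
import numpy as np
from lncass import LNCASSRegression
from lncass.synthetic import default_scenarios, generate_grouped_regression

# the default simulation scenario: n=100, p=20 in 5 groups of 4;
# group g1 shares one coefficient (2.0), g2 is heterogeneous, g3-g5 are zero
config = default_scenarios()[0]
data, truth = generate_grouped_regression(config)

model = LNCASSRegression(groups=truth.groups.assignment, random_state=11)
model.fit(data.X, data.y)

print("max split R-hat:", round(model.rhat_max_, 3))
print("posterior median coefficients (first 8):")
print(np.round(model.coef_[:8], 2))
print("mean inclusion weights (first 8):")
print(np.round(model.inclusion_[:8], 2))
```

Output:

```
max split R-hat: 1.042
posterior median coefficients (first 8):
[ 1.74  1.79  1.79  1.81  3.31  1.55 -1.54  0.47]
mean inclusion weights (first 8):
[0.69 0.69 0.69 0.69 0.83 0.83 0.83 0.83]
```

The first four coefficients (the shared group, truth 2.0) and the
heterogeneous group (truth 3, 1.5, −2, 0.5) are recovered; the twelve
coefficients of the zero groups (not shown) have medians rounding to 0.
Against this truth the fit attains sparsity-recovery AUC 1.0 and
MAE ≈ 0.09, versus MAE ≈ 0.34 for ordinary least squares on the same
data.

A command-line front end mirrors the library:

```bash
lncass simulate --setting p20 --out sim/          # write X, y, truth, groups
lncass fit --x sim/X.csv --y sim/y.csv --model grouped --groups sim/groups.csv
lncass study --settings p20 --out study/          # recovery scores per method
lncass screen --x expr.csv --y labels.csv --k 500 # univariate Wald screen
lncass evaluate --x X.csv --y y.csv --model gam --scheme loocv --class-balance
```

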
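"""Seeded synthetic-data generators and the parameter-recovery study driver.

The grouped linear-regression generator reproduces the structure of the
parameter-recovery experiment: n = 100 observations, design sampled from a
unit Latin hypercube, grouped coefficients exhibiting three behaviours —
whole groups of exact zeros, one group sharing a single coefficient value,
and one heterogeneous group — and i.i.d. zero-mean Gaussian noise on the
response.  The GAM scene is a smaller fixture with one quadratic effect, one
linear effect and eight null covariates feeding a Bernoulli-logit response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .inference import run_mcmc, summarize
from .metrics import mae, sparsity_recovery_auc
from .models import (
    GroupStructure,
    RegressionDataset,
    build_flat_model,
    build_grouped_model,
)
from .priors import LNCASSHyperparams, sigm

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "StudyResult",
    "latin_hypercube",
    "generate_grouped_regression",
    "default_scenarios",
    "run_simulation_study",
    "generate_gam_scene",
    "GAMScene",
]


def latin_hypercube(n: int, p: int, seed) -> np.ndarray:
    """n x p unit Latin hypercube: each column has exactly one point per bin
    [i/n, (i+1)/n), uniform within the bin, with independent permutations
    across columns."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.empty((n, p))
    for j in range(p):
        perm = rng.permutation(n)
        X[:, j] = (perm + rng.random(n)) / n
    return X


@dataclass
class SimulationConfig:
    """One grouped-regression scenario: sizes, truth and noise level."""

    n: int
    p: int
    group_sizes: Sequence[int]
    beta_true: np.ndarray
    beta0_true: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if sum(self.group_sizes) != self.p:
            raise ValueError(
                f"group_sizes sum to {sum(self.group_sizes)}, expected p={self.p}"
            )
        if self.beta_true.shape != (self.p,):
            raise ValueError("beta_true must have length p")
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be positive")

    def group_structure(self) -> GroupStructure:
        labels = []
        for g, size in enumerate(self.group_sizes):
            labels += [f"g{g + 1}"] * size
        return GroupStructure(assignment=labels)


@dataclass
class SimulationTruth:
    """Ground truth accompanying a generated dataset."""

    beta_true: np.ndarray
    beta0_true: float
    groups: GroupStructure
    group_behaviour: dict[str, str]  # label -> zero | shared | heterogeneous


def _group_behaviour(config: SimulationConfig, groups: GroupStructure) -> dict[str, str]:
    out = {}
    for g in groups.groups:
        vals = config.beta_true[groups.member_indices(g)]
        if np.all(vals == 0):
            out[g] = "zero"
        elif np.unique(vals).size == 1:
            out[g] = "shared"
        else:
            out[g] = "heterogeneous"
    return out


def generate_grouped_regression(
    config: SimulationConfig,
) -> tuple[RegressionDataset, SimulationTruth]:
    """Draw (X, y) from y = beta0 + X beta + eps, eps ~ N(0, noise_sd^2)."""
    X = latin_hypercube(config.n, config.p, np.random.SeedSequence([config.seed, 0]))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    eps = rng.normal(0.0, config.noise_sd, size=config.n)
    y = config.beta0_true + X @ config.beta_true + eps
    data = RegressionDataset(X, y, family="gaussian")
    groups = config.group_structure()
    truth = SimulationTruth(
        beta_true=config.beta_true.copy(),
        beta0_true=config.beta0_true,
        groups=groups,
        group_behaviour=_group_behaviour(config, groups),
    )
    return data, truth


# Editable fixture coefficients for the three default settings.  Each setting
# has n = 100 and exhibits one shared-coefficient group, one heterogeneous
# group and all remaining groups exactly zero.
_SHARED = 2.0
_HETERO_BASE = [3.0, 1.5, -2.0, 0.5, -1.0, 2.5, 0.75, -1.5]


def default_scenarios(noise_sd: float = 1.0, seed: int = 0) -> list[SimulationConfig]:
    """The three default settings: (n, p) = (100, 20), (100, 70), (100, 120)."""
    scenarios = []
    layouts = [
        (20, [4] * 5),
        (70, [7] * 10),
        (120, [8] * 15),
    ]
    for p, sizes in layouts:
        beta = np.zeros(p)
        beta[: sizes[0]] = _SHARED  # first group: shared coefficient
        hetero = _HETERO_BASE[: sizes[1]]
        beta[sizes[0] : sizes[0] + sizes[1]] = hetero  # second group: heterogeneous
        scenarios.append(
            SimulationConfig(
                n=100,
                p=p,
                group_sizes=sizes,
                beta_true=beta,
                beta0_true=1.0,
                noise_sd=noise_sd,
                seed=seed + p,  # distinct data per setting, reproducible overall
            )
        )
    return scenarios


@dataclass
class StudyResult:
    """Per-(method, setting) recovery scores with the fitted medians."""

    table: pd.DataFrame  # columns: method, n, p, auc, mae
    estimates: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    configs: list[SimulationConfig] = field(default_factory=list)
    rhat_max: dict[tuple[str, int], float] = field(default_factory=dict)


def ols_estimate(data: RegressionDataset) -> tuple[float, np.ndarray]:
    """Closed-form least squares with intercept; requires p < n."""
    n, p = data.X.shape
    if p >= n:
        raise ValueError(
            f"ordinary least squares requires p < n (got p={p}, n={n}); "
            "the problem is not well defined when p > n"
        )
    A = np.column_stack([np.ones(n), data.X])
    coef, *_ = np.linalg.lstsq(A, data.y, rcond=None)
    return float(coef[0]), coef[1:]


def run_simulation_study(
    scenarios: Sequence[SimulationConfig],
    methods: Sequence[str] = ("lncass_grouped", "lncass_flat", "ols"),
    seed: int = 0,
    *,
    hyper: LNCASSHyperparams | None = None,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    misassign_one: bool = False,
) -> StudyResult:
    """Fit each method on each scenario and score parameter recovery.

    ``misassign_one`` flips the group label of the first predictor of the
    heterogeneous group to the first zero group before fitting the grouped
    model — a deliberate misspecification probe.
    """
    hyper = hyper or LNCASSHyperparams()
    rows = []
    estimates: dict[tuple[str, int], np.ndarray] = {}
    rhat_max: dict[tuple[str, int], float] = {}
    for config in scenarios:
        data, truth = generate_grouped_regression(config)
        for method in methods:
            if method == "ols":
                if config.p >= config.n:
                    raise ValueError(
                        "ordinary least squares requires p < n; it was tested only "
                        f"for the p < n cases (requested p={config.p}, n={config.n})"
                    )
                _, beta_hat = ols_estimate(data)
                rh = np.nan
            elif method in ("lncass_flat", "lncass_grouped"):
                if method == "lncass_flat":
                    model = build_flat_model(data, hyper)
                else:
                    groups = truth.groups
                    if misassign_one:
                        assignment = list(groups.assignment)
                        hetero = [
                            g for g, b in truth.group_behaviour.items()
                            if b == "heterogeneous"
                        ][0]
                        zero = [
                            g for g, b in truth.group_behaviour.items() if b == "zero"
                        ][0]
                        j = groups.member_indices(hetero)[0]
                        assignment[j] = zero
                        groups = GroupStructure(assignment=assignment)
                    model = build_grouped_model(data, groups, hyper)
                samples = run_mcmc(
                    model, chains=chains, warmup=warmup, draws=draws, seed=seed
                )
                summary = summarize(samples)
                beta_hat = summary.beta_median
                rh = (
                    float(summary.rhat.max()) if summary.rhat is not None else np.nan
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append(
                {
                    "method": method,
                    "n": config.n,
                    "p": config.p,
                    "auc": sparsity_recovery_auc(beta_hat, truth.beta_true),
                    "mae": mae(beta_hat, truth.beta_true),
                }
            )
            estimates[(method, config.p)] = beta_hat
            rhat_max[(method, config.p)] = rh
    return StudyResult(
        table=pd.DataFrame(rows),
        estimates=estimates,
        configs=list(scenarios),
        rhat_max=rhat_max,
    )


@dataclass
class GAMScene:
    """Binomial GAM fixture with known effect functions."""

    data: RegressionDataset
    truth_functions: list[Callable[[np.ndarray], np.ndarray]]
    signal_covariates: tuple[int, int] = (0, 1)  # (quadratic, linear)

    def truth_on_grid(self, grid: np.ndarray) -> np.ndarray:
        return np.stack([f(np.asarray(grid, dtype=float)) for f in self.truth_functions])


def _gam_truths() -> list[Callable[[np.ndarray], np.ndarray]]:
    # centred so each effect has zero mean over U(0,1); intercept truth is 0
    quad = lambda x: 16.0 * (x - 0.5) ** 2 - 16.0 / 12.0  # noqa: E731
    lin = lambda x: 5.0 * (x - 0.5)  # noqa: E731
    null = lambda x: np.zeros_like(x)  # noqa: E731
    return [quad, lin] + [null] * 8


def generate_gam_scene(n: int, seed) -> GAMScene:
    """10 uniform covariates; logit of P(y=1) = quadratic(x1) + linear(x2)."""
    if n < 50:
        raise ValueError("need n >= 50 for a usable GAM scene")
    rng = np.random.default_rng(seed)
    X = rng.random((n, 10))
    fns = _gam_truths()
    eta = sum(f(X[:, i]) for i, f in enumerate(fns))
    y = (rng.random(n) < sigm(eta)).astype(float)
    data = RegressionDataset(X, y, family="binomial")
    return GAMScene(data=data, truth_functions=fns)
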
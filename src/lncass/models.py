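"""Joint log-densities for the three LN-CASS regression variants.

Each builder returns a :class:`ModelSpec`: a joint log-density over a flat
vector of unconstrained latents together with its analytic gradient and a
deterministic map from latents to interpretable quantities (intercept,
regression coefficients, inclusion weights, noise scale).

All latents are non-centred: every stochastic latent carries a standard-normal
prior and constrained quantities are deterministic transforms, e.g. the
inclusion weight of predictor j is ``lambda_j = sigm(mu_lambda +
sigma_lambda * u_j)`` with ``u_j ~ N(0, 1)``.  This keeps the posterior
geometry friendly to gradient-based samplers even when the logit-normal is
sharply U-shaped.

Variants
--------
flat
    ``beta_j = tau * lambda_j * z_j`` per predictor; gaussian or
    binomial(logit) likelihood.
grouped
    complexity ladder *no effect -> shared group effect -> individual effect*:
    ``beta_gj = tau * lambda_g * (z_g + lambda_gj * w_gj)`` so that
    ``lambda_g -> 0`` excludes the whole group and ``lambda_gj -> 0`` collapses
    member j onto the shared group coefficient.
gam
    complexity ladder *no effect -> linear effect -> nonlinear effect* for a
    logit-link GAM on a linear + hinge basis: linear coefficient
    ``tau * lambda_i * z_i``, knot-k coefficient
    ``tau * lambda_i * lambda_i^nl * w_ik``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._kernels import flat_kernel, gam_kernel, grouped_kernel
from .priors import LNCASSHyperparams, sigm

__all__ = [
    "RegressionDataset",
    "GroupStructure",
    "GAMConfig",
    "ModelSpec",
    "build_flat_model",
    "build_grouped_model",
    "build_gam_basis",
    "build_hierarchical_gam",
    "extract_effect_curves",
    "EffectCurves",
]

_LOG2PI = np.log(2.0 * np.pi)

# vague-but-proper nuisance priors: intercept N(0, 10^2), noise sd half-normal(0, 5)
INTERCEPT_SD = 10.0
NOISE_SD_SCALE = 5.0


@dataclass
class RegressionDataset:
    """Design matrix, response and family tag for one regression problem."""

    X: np.ndarray
    y: np.ndarray
    family: str = "gaussian"
    predictor_names: Sequence[str] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (rows = observations)")
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 and p >= 1, got n={n}, p={p}")
        if self.y.shape != (n,):
            raise ValueError(f"y must have length n={n}, got shape {self.y.shape}")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError(
                "X and y must be fully observed and finite; impute missing values upstream"
            )
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"family must be 'gaussian' or 'binomial', got {self.family!r}")
        if self.family == "binomial" and not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("binomial response must contain only 0/1 values")
        if self.predictor_names is None:
            self.predictor_names = [f"x{j}" for j in range(p)]
        else:
            self.predictor_names = [str(s) for s in self.predictor_names]
            if len(self.predictor_names) != p:
                raise ValueError("predictor_names length must equal p")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows=None, cols=None) -> "RegressionDataset":
        X, y, names = self.X, self.y, list(self.predictor_names)
        if rows is not None:
            X, y = X[rows], y[rows]
        if cols is not None:
            X = X[:, cols]
            names = [names[j] for j in np.atleast_1d(cols)]
        return RegressionDataset(X, y, family=self.family, predictor_names=names)


@dataclass
class GroupStructure:
    """Partition of the predictors into named groups."""

    assignment: Sequence[str]
    groups: Sequence[str] | None = None

    def __post_init__(self):
        self.assignment = [str(g) for g in self.assignment]
        if len(self.assignment) == 0:
            raise ValueError("assignment must cover at least one predictor")
        seen = list(dict.fromkeys(self.assignment))
        if self.groups is None:
            self.groups = seen
        else:
            self.groups = [str(g) for g in self.groups]
            if set(self.groups) != set(seen):
                raise ValueError("groups must be exactly the distinct assignment labels")
        for g in self.groups:
            if self.assignment.count(g) == 0:
                raise ValueError(f"group {g!r} has zero members")

    @property
    def p(self) -> int:
        return len(self.assignment)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def member_indices(self, group: str) -> np.ndarray:
        return np.array([j for j, g in enumerate(self.assignment) if g == group], dtype=int)

    def group_index_of(self) -> np.ndarray:
        """Length-p vector mapping predictor j to the index of its group."""
        lut = {g: i for i, g in enumerate(self.groups)}
        return np.array([lut[g] for g in self.assignment], dtype=int)

    @classmethod
    def from_csv(cls, path, predictor_names: Sequence[str]) -> "GroupStructure":
        """Read a two-column (predictor_name, group_label) map with header."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("group map must have two columns: predictor_name, group_label")
        mapping = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        unknown = [n for n in predictor_names if n not in mapping]
        if unknown:
            raise ValueError(f"group map missing predictors: {unknown}")
        return cls(assignment=[mapping[n] for n in predictor_names])


@dataclass
class GAMConfig:
    """Knot layout for the linear + hinge basis expansion on [0, 1]."""

    n_knots: int = 5
    knot_positions: np.ndarray | None = None

    def __post_init__(self):
        if self.n_knots < 0:
            raise ValueError("n_knots must be >= 0")
        if self.knot_positions is None:
            k = self.n_knots
            self.knot_positions = np.arange(1, k + 1) / (k + 1.0)
        else:
            self.knot_positions = np.asarray(self.knot_positions, dtype=float)
            if self.knot_positions.shape != (self.n_knots,):
                raise ValueError("knot_positions must have length n_knots")
            if np.any(np.diff(self.knot_positions) <= 0):
                raise ValueError("knots must be strictly increasing")
            if self.n_knots and (
                self.knot_positions[0] <= 0.0 or self.knot_positions[-1] >= 1.0
            ):
                raise ValueError("knots must lie strictly inside (0, 1)")


@dataclass
class ModelSpec:
    """A fully specified joint log-density over named unconstrained latents.

    ``log_density`` and ``logp_and_grad`` act on a flat latent vector of
    length ``dim``; ``coefficient_map`` is vectorized over leading axes and
    returns a dict with (at least) ``beta0``, ``beta`` and the top-layer
    inclusion weights ``lambda_top``.
    """

    dim: int
    latent_names: list[str]
    blocks: dict[str, slice]
    log_density: Callable[[np.ndarray], float]
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]]
    coefficient_map: Callable[[np.ndarray], dict]
    variant: str
    family: str
    predictor_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.latent_names) != self.dim:
            raise ValueError("latent_names must have one entry per latent scalar")


def build_flat_model(
    data: RegressionDataset,
    hyper: LNCASSHyperparams,
    *,
    freeze_lambda: bool = False,
    noise_sd: float | None = None,
    prior_only: bool = False,
) -> ModelSpec:
    """Flat LN-CASS regression: ``beta_j = tau * lambda_j * z_j`` per predictor.

    Parameters
    ----------
    freeze_lambda : bool
        Fix every inclusion weight at 1, removing the gate latents; the model
        collapses to ridge-like regression with slab prior N(0, tau^2).
    noise_sd : float, optional
        Fix the gaussian noise scale instead of assigning it a half-normal
        prior (gaussian family only).
    prior_only : bool
        Drop the likelihood term; sampling then targets the prior (used for
        validating the sampler against direct prior simulation).
    """
    X, y, family = data.X, data.y, data.family
    n, p = X.shape
    tau, mu_l, sig_l = hyper.tau, hyper.mu_lambda, hyper.sigma_lambda
    gaussian = family == "gaussian"
    if not gaussian and noise_sd is not None:
        raise ValueError("noise_sd applies to the gaussian family only")
    sample_sigma = gaussian and noise_sd is None

    names = ["intercept"]
    blocks = {"intercept": slice(0, 1)}
    pos = 1
    if sample_sigma:
        blocks["noise"] = slice(pos, pos + 1)
        names.append("noise.sigma")
        pos += 1
    if not freeze_lambda:
        blocks["gate"] = slice(pos, pos + p)
        names += [f"gate.u.{nm}" for nm in data.predictor_names]
        pos += p
    blocks["effect"] = slice(pos, pos + p)
    names += [f"effect.z.{nm}" for nm in data.predictor_names]
    pos += p
    dim = pos
    sl_b0 = blocks["intercept"]
    sl_sig = blocks.get("noise")
    sl_u = blocks.get("gate")
    sl_z = blocks["effect"]

    def unpack(x):
        b0 = INTERCEPT_SD * x[..., 0]
        if sl_u is not None:
            lam = sigm(mu_l + sig_l * x[..., sl_u])
        else:
            lam = np.ones(x.shape[:-1] + (p,))
        z = x[..., sl_z]
        beta = tau * lam * z
        out = {"beta0": b0, "beta": beta, "lambda_top": lam, "lambda": lam}
        if sample_sigma:
            out["sigma_eps"] = np.exp(x[..., sl_sig.start])
        elif gaussian:
            out["sigma_eps"] = np.broadcast_to(noise_sd, x.shape[:-1]).copy()
        return out

    Xc = np.ascontiguousarray(X)
    yc = np.ascontiguousarray(y)

    def logp_and_grad(x):
        grad = np.empty(dim)
        logp = flat_kernel(
            x, Xc, yc, tau, mu_l, sig_l, INTERCEPT_SD, NOISE_SD_SCALE,
            gaussian, sample_sigma, freeze_lambda, prior_only,
            float(noise_sd if noise_sd is not None else 1.0), grad,
        )
        return logp, grad

    return ModelSpec(
        dim=dim,
        latent_names=names,
        blocks=blocks,
        log_density=lambda x: logp_and_grad(x)[0],
        logp_and_grad=logp_and_grad,
        coefficient_map=unpack,
        variant="flat",
        family=family,
        predictor_names=list(data.predictor_names),
        meta={
            "hyper": hyper,
            "p": p,
            "n": n,
            "freeze_lambda": freeze_lambda,
            "noise_sd": noise_sd,
            "prior_only": prior_only,
        },
    )


def build_grouped_model(
    data: RegressionDataset,
    groups: GroupStructure,
    hyper: LNCASSHyperparams,
) -> ModelSpec:
    """Grouped LN-CASS: ``beta_gj = tau * lambda_g * (z_g + lambda_gj * w_gj)``.

    Inclusion layers compose multiplicatively: the group gate ``lambda_g``
    switches the whole group, the member gate ``lambda_gj`` switches member
    j's deviation ``w_gj`` from the shared group coefficient ``z_g``.
    """
    X, y, family = data.X, data.y, data.family
    n, p = X.shape
    if groups.p != p:
        raise ValueError(f"group structure covers {groups.p} predictors, data has {p}")
    G = groups.n_groups
    gidx = groups.group_index_of()  # predictor -> group index
    tau, mu_l, sig_l = hyper.tau, hyper.mu_lambda, hyper.sigma_lambda
    gaussian = family == "gaussian"

    names = ["intercept"]
    blocks = {"intercept": slice(0, 1)}
    pos = 1
    if gaussian:
        blocks["noise"] = slice(pos, pos + 1)
        names.append("noise.sigma")
        pos += 1
    blocks["group_gate"] = slice(pos, pos + G)
    names += [f"group_gate.u.{g}" for g in groups.groups]
    pos += G
    blocks["group_effect"] = slice(pos, pos + G)
    names += [f"group_effect.z.{g}" for g in groups.groups]
    pos += G
    blocks["member_gate"] = slice(pos, pos + p)
    names += [f"member_gate.u.{nm}" for nm in data.predictor_names]
    pos += p
    blocks["member_dev"] = slice(pos, pos + p)
    names += [f"member_dev.w.{nm}" for nm in data.predictor_names]
    pos += p
    dim = pos
    sl_sig = blocks.get("noise")
    sl_ug, sl_zg = blocks["group_gate"], blocks["group_effect"]
    sl_um, sl_w = blocks["member_gate"], blocks["member_dev"]

    def unpack(x):
        b0 = INTERCEPT_SD * x[..., 0]
        lam_g = sigm(mu_l + sig_l * x[..., sl_ug])
        z_g = x[..., sl_zg]
        lam_m = sigm(mu_l + sig_l * x[..., sl_um])
        w = x[..., sl_w]
        beta = tau * lam_g[..., gidx] * (z_g[..., gidx] + lam_m * w)
        out = {
            "beta0": b0,
            "beta": beta,
            "lambda_top": lam_g[..., gidx],
            "lambda_group": lam_g,
            "lambda_member": lam_m,
        }
        if gaussian:
            out["sigma_eps"] = np.exp(x[..., sl_sig.start])
        return out

    Xc = np.ascontiguousarray(X)
    yc = np.ascontiguousarray(y)
    gidx_c = np.ascontiguousarray(gidx, dtype=np.int64)

    def logp_and_grad(x):
        grad = np.empty(dim)
        logp = grouped_kernel(
            x, Xc, yc, gidx_c, G, tau, mu_l, sig_l, INTERCEPT_SD,
            NOISE_SD_SCALE, gaussian, grad,
        )
        return logp, grad

    return ModelSpec(
        dim=dim,
        latent_names=names,
        blocks=blocks,
        log_density=lambda x: logp_and_grad(x)[0],
        logp_and_grad=logp_and_grad,
        coefficient_map=unpack,
        variant="grouped",
        family=family,
        predictor_names=list(data.predictor_names),
        meta={"hyper": hyper, "p": p, "n": n, "groups": groups},
    )


def build_gam_basis(x, config: GAMConfig) -> np.ndarray:
    """Linear + hinge basis for one covariate on [0, 1].

    Column 0 is the identity x; column k (k >= 1) is the hinge
    ``max(0, x - kappa_k)`` at knot ``kappa_k``.
    """
    x = np.asarray(x, dtype=float)
    bad = np.flatnonzero((x < 0.0) | (x > 1.0))
    if bad.size:
        raise ValueError(
            f"covariate values must lie in [0, 1]; offending indices: {bad[:10].tolist()}"
        )
    cols = [x]
    for kappa in config.knot_positions:
        cols.append(np.maximum(0.0, x - kappa))
    return np.column_stack(cols)


def build_hierarchical_gam(
    data: RegressionDataset,
    hyper: LNCASSHyperparams,
    config: GAMConfig,
) -> ModelSpec:
    """Hierarchical LN-CASS GAM with logit link.

    Per covariate i: inclusion gate ``lambda_i``, linear latent ``z_i``,
    nonlinearity gate ``lambda_i^nl`` and per-knot latents ``w_ik``; the
    effect curve is ``f_i(x) = tau*lambda_i*z_i * x +
    sum_k tau*lambda_i*lambda_i^nl*w_ik * max(0, x - kappa_k)``.
    """
    if data.family != "binomial":
        raise ValueError(
            "the hierarchical GAM supports the binomial family (logit link) only"
        )
    X, y = data.X, data.y
    n, p = X.shape
    K = config.n_knots
    tau, mu_l, sig_l = hyper.tau, hyper.mu_lambda, hyper.sigma_lambda

    # full basis matrix, covariate-major column blocks of width 1+K
    B = np.concatenate([build_gam_basis(X[:, i], config) for i in range(p)], axis=1)

    names = ["intercept"]
    blocks = {"intercept": slice(0, 1)}
    pos = 1
    blocks["gate"] = slice(pos, pos + p)
    names += [f"gate.u.{nm}" for nm in data.predictor_names]
    pos += p
    blocks["linear"] = slice(pos, pos + p)
    names += [f"linear.z.{nm}" for nm in data.predictor_names]
    pos += p
    if K > 0:
        blocks["nl_gate"] = slice(pos, pos + p)
        names += [f"nl_gate.v.{nm}" for nm in data.predictor_names]
        pos += p
        blocks["knot"] = slice(pos, pos + p * K)
        names += [
            f"knot.w.{nm}.{k}" for nm in data.predictor_names for k in range(K)
        ]
        pos += p * K
    dim = pos
    sl_u, sl_z = blocks["gate"], blocks["linear"]
    sl_v = blocks.get("nl_gate")
    sl_w = blocks.get("knot")

    def coef_vector(lam, z, lam_nl, w):
        """Basis coefficients in covariate-major order, vectorized over leads."""
        lin = tau * lam * z  # (..., p)
        if K == 0:
            return lin[..., :, None].reshape(*lin.shape[:-1], p)
        knot = tau * lam[..., :, None] * lam_nl[..., :, None] * w  # (..., p, K)
        full = np.concatenate([lin[..., :, None], knot], axis=-1)  # (..., p, 1+K)
        return full.reshape(*full.shape[:-2], p * (1 + K))

    def unpack(x):
        b0 = INTERCEPT_SD * x[..., 0]
        lam = sigm(mu_l + sig_l * x[..., sl_u])
        z = x[..., sl_z]
        if K > 0:
            lam_nl = sigm(mu_l + sig_l * x[..., sl_v])
            w = x[..., sl_w].reshape(*x.shape[:-1], p, K)
        else:
            lam_nl = np.ones_like(lam)
            w = np.zeros(x.shape[:-1] + (p, 0))
        out = {
            "beta0": b0,
            "beta": coef_vector(lam, z, lam_nl, w),
            "lambda_top": lam,
            "lambda_nl": lam_nl,
            "linear_coef": tau * lam * z,
            "knot_coef": tau * lam[..., :, None] * lam_nl[..., :, None] * w,
        }
        return out

    Bc = np.ascontiguousarray(B)
    yc = np.ascontiguousarray(y)

    def logp_and_grad(x):
        grad = np.empty(dim)
        logp = gam_kernel(x, Bc, yc, K, tau, mu_l, sig_l, INTERCEPT_SD, grad)
        return logp, grad

    return ModelSpec(
        dim=dim,
        latent_names=names,
        blocks=blocks,
        log_density=lambda x: logp_and_grad(x)[0],
        logp_and_grad=logp_and_grad,
        coefficient_map=unpack,
        variant="gam",
        family="binomial",
        predictor_names=list(data.predictor_names),
        meta={"hyper": hyper, "p": p, "n": n, "config": config, "basis": B},
    )


@dataclass
class EffectCurves:
    """Posterior pointwise summaries of the per-covariate effect curves."""

    grid: np.ndarray
    mean: np.ndarray  # (p, len(grid))
    lower: np.ndarray  # 5th percentile
    upper: np.ndarray  # 95th percentile
    predictor_names: list[str]


def extract_effect_curves(samples, config: GAMConfig, grid) -> EffectCurves:
    """Pointwise posterior mean and central 90% band of each f_i on a grid.

    Values are raw linear combinations of the basis columns — no smoothing.
    """
    grid = np.asarray(grid, dtype=float)
    Bg = build_gam_basis(grid, config)  # (G, 1+K)
    der = samples.derived
    if "linear_coef" not in der or "knot_coef" not in der:
        raise ValueError("samples were not produced by a GAM model")
    lin = der["linear_coef"].reshape(-1, der["linear_coef"].shape[-1])  # (S, p)
    knot = der["knot_coef"].reshape(-1, *der["knot_coef"].shape[-2:])  # (S, p, K)
    if knot.shape[-1] != config.n_knots:
        raise ValueError(
            f"config has {config.n_knots} knots but samples carry {knot.shape[-1]}"
        )
    coef = np.concatenate([lin[:, :, None], knot], axis=2)  # (S, p, 1+K)
    curves = np.einsum("spk,gk->spg", coef, Bg)
    return EffectCurves(
        grid=grid,
        mean=curves.mean(axis=0),
        lower=np.quantile(curves, 0.05, axis=0),
        upper=np.quantile(curves, 0.95, axis=0),
        predictor_names=list(samples.model.predictor_names),
    )
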
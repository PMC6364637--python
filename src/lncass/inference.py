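"""MCMC driving, convergence diagnostics and posterior summaries.

``run_mcmc`` runs independent NUTS chains over a :class:`~lncass.models.ModelSpec`
and returns a :class:`PosteriorSamples` container holding per-chain latent
draws plus the derived coefficient-scale quantities.  ``gelman_rubin``
computes the split-R-hat statistic; ``summarize`` produces the medians,
intervals and mean inclusion weights used for reporting and hard selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .models import ModelSpec
from .sampler import NUTSDiagnostics, sample_nuts

__all__ = [
    "PosteriorSamples",
    "PosteriorSummary",
    "run_mcmc",
    "gelman_rubin",
    "split_rhat",
    "summarize",
    "select_top_k",
]


@dataclass
class PosteriorSamples:
    """Per-chain, per-draw latent arrays plus derived coefficient draws."""

    model: ModelSpec
    latents: np.ndarray  # (chains, draws, dim)
    seed: int
    warmup: int
    diagnostics: list[NUTSDiagnostics] = field(default_factory=list)

    def __post_init__(self):
        if self.latents.ndim != 3 or self.latents.shape[2] != self.model.dim:
            raise ValueError("latents must have shape (chains, draws, dim)")

    @property
    def chains(self) -> int:
        return self.latents.shape[0]

    @property
    def draws(self) -> int:
        return self.latents.shape[1]

    @cached_property
    def derived(self) -> dict:
        """coefficient_map applied draw-wise: dict of (chains, draws, ...) arrays."""
        return self.model.coefficient_map(self.latents)

    def scalar_parameters(self) -> dict[str, np.ndarray]:
        """Named scalar chains: latents plus derived beta0/beta/lambda layers.

        Each value has shape (chains, draws).
        """
        out = {}
        for i, nm in enumerate(self.model.latent_names):
            out[nm] = self.latents[:, :, i]
        der = self.derived
        out["beta0"] = der["beta0"]
        names = self.model.predictor_names
        beta = der["beta"]
        if beta.shape[-1] == len(names):
            for j, nm in enumerate(names):
                out[f"beta.{nm}"] = beta[:, :, j]
        else:  # GAM basis coefficients: report the per-covariate linear part
            for j, nm in enumerate(names):
                out[f"beta_linear.{nm}"] = der["linear_coef"][:, :, j]
        for layer in ("lambda_top", "lambda_nl", "lambda_group", "lambda_member"):
            if layer in der:
                arr = der[layer]
                labels = (
                    self.model.meta["groups"].groups
                    if layer == "lambda_group"
                    else names
                )
                for j, nm in enumerate(labels[: arr.shape[-1]]):
                    out[f"{layer}.{nm}"] = arr[:, :, j]
        if "sigma_eps" in der:
            out["sigma_eps"] = der["sigma_eps"]
        return out

    def to_draws_frame(self) -> pd.DataFrame:
        """Long-format draws table (chain, draw, parameter, value)."""
        rows = []
        for name, arr in self.scalar_parameters().items():
            c, d = np.meshgrid(
                np.arange(self.chains), np.arange(self.draws), indexing="ij"
            )
            rows.append(
                pd.DataFrame(
                    {
                        "chain": c.ravel(),
                        "draw": d.ravel(),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_mcmc(
    model: ModelSpec,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    *,
    target_accept: float = 0.95,
    max_depth: int = 8,
) -> PosteriorSamples:
    """Sample the model with NUTS; chains run sequentially and independently.

    Reproducible: a fixed (seed, chains, warmup, draws) quadruple yields
    identical draws.  Initialization retries up to three reseeds per chain if
    the sampler starts in a region of non-finite density.
    """
    if chains < 1 or draws < 1:
        raise ValueError("chains and draws must be >= 1")
    latents = np.empty((chains, draws, model.dim))
    diags = []
    for c in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), c]))
        out, diag = sample_nuts(
            model.logp_and_grad,
            model.dim,
            warmup=warmup,
            draws=draws,
            rng=rng,
            target_accept=target_accept,
            max_depth=max_depth,
        )
        latents[c] = out
        diags.append(diag)
    return PosteriorSamples(
        model=model, latents=latents, seed=int(seed), warmup=warmup, diagnostics=diags
    )


def split_rhat(chains_draws: np.ndarray) -> float:
    """Split-R-hat of one scalar parameter from a (chains, draws) array.

    Each chain is halved, then the classic Gelman–Rubin between/within
    variance ratio is computed on the 2*chains half-chains.
    """
    arr = np.asarray(chains_draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    m, n = arr.shape
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain for split-R-hat")
    splits = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    means = splits.mean(axis=1)
    variances = splits.var(axis=1, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def gelman_rubin(samples: PosteriorSamples) -> pd.Series:
    """Per-parameter split-R-hat over latents and derived quantities."""
    if samples.chains < 2:
        raise ValueError(
            "R-hat needs at least 2 chains; run more chains (the split statistic "
            "is computed per half-chain, but cross-chain disagreement requires "
            "multiple independent chains)"
        )
    vals = {
        name: split_rhat(arr) for name, arr in samples.scalar_parameters().items()
    }
    return pd.Series(vals, name="rhat")


@dataclass
class PosteriorSummary:
    """Coefficient-scale posterior summaries.

    ``coefficients`` rows are the intercept followed by the regression
    coefficients, with columns median / mean / q5 / q95.  ``inclusion`` holds
    the per-predictor posterior mean of the top-layer inclusion weight.
    Summaries are computed on the per-draw derived quantities (map first,
    summarize second), never on summaries of raw latents.
    """

    coefficients: pd.DataFrame
    inclusion: pd.Series
    rhat: pd.Series | None
    extra: dict = field(default_factory=dict)

    @property
    def beta_median(self) -> np.ndarray:
        return self.coefficients["median"].to_numpy()[1:]  # drop intercept row


def summarize(samples: PosteriorSamples) -> PosteriorSummary:
    der = samples.derived
    names = samples.model.predictor_names
    beta = der["beta"].reshape(-1, der["beta"].shape[-1])
    b0 = der["beta0"].ravel()

    if beta.shape[1] == len(names):
        coef_names = list(names)
        coef_draws = beta
    else:  # GAM: summarize the per-covariate linear coefficients
        coef_names = [f"linear.{nm}" for nm in names]
        coef_draws = der["linear_coef"].reshape(-1, len(names))

    mat = np.column_stack([b0[:, None], coef_draws])
    rows = ["intercept"] + coef_names
    coefficients = pd.DataFrame(
        {
            "median": np.median(mat, axis=0),
            "mean": mat.mean(axis=0),
            "q5": np.quantile(mat, 0.05, axis=0),
            "q95": np.quantile(mat, 0.95, axis=0),
        },
        index=rows,
    )
    lam = der["lambda_top"].reshape(-1, len(names))
    inclusion = pd.Series(lam.mean(axis=0), index=list(names), name="inclusion")
    rhat = gelman_rubin(samples) if samples.chains >= 2 else None
    extra = {}
    if "sigma_eps" in der:
        extra["sigma_eps_median"] = float(np.median(der["sigma_eps"]))
    if "lambda_nl" in der:
        nl = der["lambda_nl"].reshape(-1, len(names))
        extra["lambda_nl_mean"] = pd.Series(nl.mean(axis=0), index=list(names))
    if "lambda_member" in der:
        mem = der["lambda_member"].reshape(-1, len(names))
        extra["lambda_member_mean"] = pd.Series(mem.mean(axis=0), index=list(names))
    return PosteriorSummary(
        coefficients=coefficients, inclusion=inclusion, rhat=rhat, extra=extra
    )


def select_top_k(summary: PosteriorSummary, k: int) -> np.ndarray:
    """Indices of the k largest |median| coefficients; ties -> lower index."""
    med = np.abs(summary.beta_median)
    p = med.size
    if not (1 <= k <= p):
        raise ValueError(f"k must lie in [1, {p}], got {k}")
    order = np.argsort(-med, kind="stable")  # stable: equal values keep index order
    return np.sort(order[:k])
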
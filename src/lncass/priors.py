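"""Logit-normal machinery and the LN-CASS coefficient construction.

The LN-CASS (logit-normal continuous analogue of the spike-and-slab) prior
replaces the Bernoulli inclusion indicator of the classical spike-and-slab
mixture with a continuous, U-shaped logit-normal weight ``lambda`` on (0, 1).
A regression coefficient is then the deterministic product

    beta = tau * lambda * z,        z ~ N(0, 1),
    lambda = sigm(eta),             eta ~ N(mu_lambda, sigma_lambda**2),

so every latent is (conditionally) standard normal after rescaling, which is
what makes the posterior fully continuous and amenable to gradient-based MCMC.
``tau`` is the slab standard deviation; ``sigm(mu_lambda)`` is the prior
median inclusion weight; ``sigma_lambda`` controls how sharply the weight
concentrates at the endpoints 0 and 1 (larger = closer to a true
spike-and-slab).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "sigm",
    "logit",
    "LogitNormalParams",
    "LNCASSHyperparams",
    "logit_normal_pdf",
    "logit_normal_cdf",
    "sample_logit_normal",
    "lncass_coefficient",
    "sample_lncass_prior",
    "sample_spike_slab",
]

# clamp for lambda before any logit/log; avoids overflow at sigma_lambda = 10-50
_LAM_EPS = 1e-12


def sigm(x):
    """Numerically stable logistic sigmoid 1 / (1 + exp(-x)).

    Stable for |x| well beyond 700 (no overflow: exp is only ever taken of a
    non-positive argument).
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def logit(p):
    """Inverse of :func:`sigm`; log(p / (1 - p)) with clamping at the endpoints."""
    p = np.clip(np.asarray(p, dtype=float), _LAM_EPS, 1.0 - _LAM_EPS)
    out = np.log(p) - np.log1p(-p)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class LogitNormalParams:
    """Location/scale of the underlying normal of a logit-normal variable."""

    mu: float = 0.0
    sigma: float = 10.0

    def __post_init__(self):
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class LNCASSHyperparams:
    """The three LN-CASS hyperparameters.

    Parameters
    ----------
    tau : float
        Slab standard deviation (default 5; appropriate for standardized
        predictors, where it amounts to a vague Gaussian prior on non-zero
        coefficients).
    sigma_lambda : float
        Scale of the logit-normal inclusion weight (default 10; larger values
        sharpen the spike-and-slab approximation, results are insensitive to
        increases).
    mu_lambda, a : float, optional
        Location of the logit-normal, or equivalently the prior inclusion
        probability ``a = sigm(mu_lambda)``.  Supply at most one; supplying
        both with inconsistent values is an error.  Default a = 0.5
        (mu_lambda = 0).
    """

    tau: float = 5.0
    sigma_lambda: float = 10.0
    mu_lambda: float = None  # type: ignore[assignment]
    a: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (self.sigma_lambda > 0):
            raise ValueError(f"sigma_lambda must be positive, got {self.sigma_lambda}")
        mu, a = self.mu_lambda, self.a
        if mu is None and a is None:
            mu, a = 0.0, 0.5
        elif mu is None:
            if not (0.0 < a < 1.0):
                raise ValueError(f"a must lie in (0, 1), got {a}")
            mu = logit(a)
        elif a is None:
            a = sigm(mu)
        else:
            if abs(sigm(mu) - a) > 1e-12:
                raise ValueError(
                    f"inconsistent hyperparameters: sigm(mu_lambda)={sigm(mu)!r} != a={a!r}"
                )
        object.__setattr__(self, "mu_lambda", float(mu))
        object.__setattr__(self, "a", float(a))

    @property
    def logit_normal(self) -> LogitNormalParams:
        return LogitNormalParams(mu=self.mu_lambda, sigma=self.sigma_lambda)

    def to_config(self) -> dict:
        """Flat key-value section (tau, sigma_lambda, a)."""
        return {"tau": self.tau, "sigma_lambda": self.sigma_lambda, "a": self.a}

    @classmethod
    def from_config(cls, section: dict) -> "LNCASSHyperparams":
        known = {"tau", "sigma_lambda", "mu_lambda", "a"}
        unknown = set(section) - known
        if unknown:
            raise ValueError(f"unknown hyperparameter keys: {sorted(unknown)}")
        if "mu_lambda" in section and "a" in section:
            raise ValueError("config must set exactly one of mu_lambda / a")
        return cls(**{k: float(v) for k, v in section.items()})


def logit_normal_pdf(x, params: LogitNormalParams):
    """Density of sigm(N(mu, sigma^2)) at x in (0, 1).

    Change of variables: normal pdf evaluated at logit(x), divided by the
    Jacobian x(1-x).
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("logit_normal_pdf is defined on the open interval (0, 1)")
    z = np.log(x) - np.log1p(-x)
    dens = stats.norm.pdf(z, loc=params.mu, scale=params.sigma) / (x * (1.0 - x))
    if dens.ndim == 0:
        return float(dens)
    return dens


def logit_normal_cdf(x, params: LogitNormalParams):
    """Analytic CDF Phi((logit(x) - mu) / sigma)."""
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("logit_normal_cdf is defined on the open interval (0, 1)")
    z = np.log(x) - np.log1p(-x)
    c = stats.norm.cdf(z, loc=params.mu, scale=params.sigma)
    if c.ndim == 0:
        return float(c)
    return c


def sample_logit_normal(params: LogitNormalParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` logit-normal variates as sigm of normal draws (seeded)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    draws = sigm(rng.normal(params.mu, params.sigma, size=n))
    # keep draws inside the open interval even when sigm saturates in double
    # precision (|normal draw| > ~37, routine at sigma = 50)
    return np.clip(draws, _LAM_EPS, 1.0 - _LAM_EPS)


def lncass_coefficient(z, lam, hyper: LNCASSHyperparams):
    """Deterministic map beta = tau * lambda * z; linear in both z and lambda."""
    return hyper.tau * np.asarray(lam, dtype=float) * np.asarray(z, dtype=float)


def sample_lncass_prior(hyper: LNCASSHyperparams, p: int, n_draws: int, seed):
    """Joint prior draws of (lambda, beta), each of shape (n_draws, p).

    beta is symmetric about 0 marginally; lambda is marginally logit-normal.
    """
    if p < 1 or n_draws < 1:
        raise ValueError("p and n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    eta = rng.normal(hyper.mu_lambda, hyper.sigma_lambda, size=(n_draws, p))
    lam = np.clip(sigm(eta), _LAM_EPS, 1.0 - _LAM_EPS)
    z = rng.normal(size=(n_draws, p))
    beta = lncass_coefficient(z, lam, hyper)
    return lam, beta


def sample_spike_slab(a: float, tau: float, n_draws: int, seed) -> np.ndarray:
    """Exact two-point-mixture spike-and-slab draws: the limiting oracle.

    With probability ``a`` a coefficient is drawn from the slab N(0, tau^2);
    otherwise it is exactly zero.  The LN-CASS prior converges to this
    distribution as sigma_lambda grows.
    """
    rng = np.random.default_rng(seed)
    incl = rng.random(n_draws) < a
    beta = np.where(incl, rng.normal(0.0, tau, size=n_draws), 0.0)
    return beta
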
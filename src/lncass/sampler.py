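"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A compact, dependency-free NUTS implementation (slice-sampling tree variant)
operating on a log-density with analytic gradient.  Warmup interleaves
dual-averaging step-size adaptation with windowed estimation of a diagonal
metric from the warmup draws, after which both are frozen.  Given the same
seed and inputs the sampler is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NUTSDiagnostics", "sample_nuts", "SamplerError"]

_MAX_DELTA_H = 1000.0  # divergence threshold on the energy error


class SamplerError(RuntimeError):
    """Raised when initialization fails after bounded retries."""


@dataclass
class NUTSDiagnostics:
    divergences: int
    mean_accept: float
    step_size: float
    max_tree_depth_hits: int


class _Nuts:
    def __init__(self, logp_and_grad, dim, rng, target_accept, max_depth):
        self.f = logp_and_grad
        self.dim = dim
        self.rng = rng
        self.target = target_accept
        self.max_depth = max_depth
        self.inv_mass = np.ones(dim)
        self.divergences = 0
        self.depth_hits = 0

    # -- hamiltonian pieces -------------------------------------------------
    def _kinetic(self, r):
        # overflow on a blown-up trajectory yields +inf, i.e. h = -inf, which
        # the divergence check absorbs; silence the benign warning
        with np.errstate(over="ignore"):
            return 0.5 * np.dot(r * self.inv_mass, r)

    def _leapfrog(self, x, r, g, eps):
        r = r + 0.5 * eps * g
        x = x + eps * (self.inv_mass * r)
        logp, g = self.f(x)
        r = r + 0.5 * eps * g
        return x, r, g, logp

    def _find_reasonable_eps(self, x):
        eps = 1.0
        logp0, g0 = self.f(x)
        r0 = self.rng.standard_normal(self.dim) / np.sqrt(self.inv_mass)
        h0 = logp0 - self._kinetic(r0)
        _, r1, _, logp1 = self._leapfrog(x, r0, g0, eps)
        h1 = logp1 - self._kinetic(r1)
        if not np.isfinite(h1):
            h1 = -np.inf
        a = 1.0 if h1 - h0 > np.log(0.5) else -1.0
        for _ in range(50):
            eps *= 2.0**a
            _, r1, _, logp1 = self._leapfrog(x, r0, g0, eps)
            h1 = logp1 - self._kinetic(r1)
            if not np.isfinite(h1):
                h1 = -np.inf
            if a * (h1 - h0) <= a * np.log(0.5):
                break
        return eps

    # -- tree building (Hoffman & Gelman alg. 6) ----------------------------
    def _build_tree(self, x, r, g, logu, v, depth, eps, h0):
        if depth == 0:
            x1, r1, g1, logp1 = self._leapfrog(x, r, g, v * eps)
            h1 = logp1 - self._kinetic(r1)
            if not np.isfinite(h1):
                h1 = -np.inf
            n1 = int(logu <= h1)
            s1 = int(logu < h1 + _MAX_DELTA_H)
            if s1 == 0:
                self._divergent = True
            alpha = min(1.0, np.exp(min(0.0, h1 - h0)))
            return x1, r1, g1, x1, r1, g1, x1, logp1, n1, s1, alpha, 1
        (
            xm, rm, gm, xp, rp, gp, x1, logp1, n1, s1, a1, na1
        ) = self._build_tree(x, r, g, logu, v, depth - 1, eps, h0)
        if s1 == 1:
            if v == -1:
                (
                    xm, rm, gm, _, _, _, x2, logp2, n2, s2, a2, na2
                ) = self._build_tree(xm, rm, gm, logu, v, depth - 1, eps, h0)
            else:
                (
                    _, _, _, xp, rp, gp, x2, logp2, n2, s2, a2, na2
                ) = self._build_tree(xp, rp, gp, logu, v, depth - 1, eps, h0)
            if n1 + n2 > 0 and self.rng.random() < n2 / (n1 + n2):
                x1, logp1 = x2, logp2
            a1 += a2
            na1 += na2
            dx = xp - xm
            s1 = (
                s2
                * int(np.dot(dx, self.inv_mass * rm) >= 0)
                * int(np.dot(dx, self.inv_mass * rp) >= 0)
            )
            n1 += n2
        return xm, rm, gm, xp, rp, gp, x1, logp1, n1, s1, a1, na1

    def _transition(self, x, logp, g, eps):
        r0 = self.rng.standard_normal(self.dim) / np.sqrt(self.inv_mass)
        h0 = logp - self._kinetic(r0)
        logu = h0 - self.rng.exponential()
        xm = xp = x
        rm = rp = r0
        gm = gp = g
        xnew, logpnew, gnew = x, logp, g
        n, s, depth = 1, 1, 0
        alpha_sum, n_alpha = 0.0, 0
        self._divergent = False
        while s == 1:
            v = 1 if self.rng.random() < 0.5 else -1
            if v == -1:
                (
                    xm, rm, gm, _, _, _, x1, logp1, n1, s1, a, na
                ) = self._build_tree(xm, rm, gm, logu, v, depth, eps, h0)
            else:
                (
                    _, _, _, xp, rp, gp, x1, logp1, n1, s1, a, na
                ) = self._build_tree(xp, rp, gp, logu, v, depth, eps, h0)
            if s1 == 1 and n1 > 0 and self.rng.random() < min(1.0, n1 / n):
                xnew, logpnew = x1, logp1
            alpha_sum += a
            n_alpha += na
            n += n1
            dx = xp - xm
            s = (
                s1
                * int(np.dot(dx, self.inv_mass * rm) >= 0)
                * int(np.dot(dx, self.inv_mass * rp) >= 0)
            )
            depth += 1
            if depth >= self.max_depth:
                self.depth_hits += 1
                break
        if self._divergent:
            self.divergences += 1
        logp_final, g_final = self.f(xnew)  # cheap relative to the tree; keeps state exact
        accept_stat = alpha_sum / max(n_alpha, 1)
        return xnew, logp_final, g_final, accept_stat


def sample_nuts(
    logp_and_grad,
    dim: int,
    *,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
    target_accept: float = 0.8,
    max_depth: int = 10,
    init_retries: int = 3,
):
    """Run one NUTS chain; returns (draws array (draws, dim), NUTSDiagnostics)."""
    nuts = _Nuts(logp_and_grad, dim, rng, target_accept, max_depth)

    x = None
    for attempt in range(init_retries + 1):
        cand = init if (init is not None and attempt == 0) else rng.uniform(-1, 1, dim)
        logp, g = logp_and_grad(cand)
        if np.isfinite(logp) and np.all(np.isfinite(g)):
            x = cand
            break
    if x is None:
        raise SamplerError(
            f"failed to find a finite initial point after {init_retries + 1} attempts; "
            f"last logp={logp!r}"
        )

    # dual averaging state
    def fresh_da(eps0):
        return {
            "mu": np.log(10.0 * eps0), "log_eps": np.log(eps0),
            "log_eps_bar": 0.0, "h_bar": 0.0, "t": 0,
        }

    gamma, t0, kappa = 0.05, 10.0, 0.75
    eps = nuts._find_reasonable_eps(x)
    da = fresh_da(eps)

    # Stan-like warmup windows: fast start, doubling slow windows for the
    # metric, fast tail for the step size.
    if warmup >= 150:
        fast0, fastN = 75, 50
        slow_total = warmup - fast0 - fastN
        ends, w, acc = [], 25, 0
        while acc + w < slow_total:
            ends.append(fast0 + acc + w)
            acc += w
            w *= 2
        ends.append(fast0 + slow_total)
        window_ends = set(ends)
        slow_start = fast0
    else:
        window_ends = set()
        slow_start = warmup + 1

    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    total = warmup + draws
    out = np.empty((draws, dim))
    accept_sum = 0.0

    for it in range(total):
        adapting = it < warmup
        step = np.exp(da["log_eps"]) if adapting else eps
        x, logp, g, astat = nuts._transition(x, logp, g, step)
        if adapting:
            da["t"] += 1
            t = da["t"]
            da["h_bar"] += (nuts.target - astat - da["h_bar"]) / (t + t0)
            da["log_eps"] = da["mu"] - np.sqrt(t) / gamma * da["h_bar"]
            eta = t ** (-kappa)
            da["log_eps_bar"] = eta * da["log_eps"] + (1 - eta) * da["log_eps_bar"]
            if it >= slow_start:
                welford_n += 1
                d = x - welford_mean
                welford_mean += d / welford_n
                welford_m2 += d * (x - welford_mean)
            if (it + 1) in window_ends and welford_n > 1:
                var = welford_m2 / (welford_n - 1)
                nw = welford_n
                nuts.inv_mass = var * (nw / (nw + 5.0)) + 1e-3 * (5.0 / (nw + 5.0))
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                eps0 = nuts._find_reasonable_eps(x)
                da = fresh_da(eps0)
            if it + 1 == warmup:
                eps = np.exp(da["log_eps_bar"])
        else:
            out[it - warmup] = x
            accept_sum += astat

    diag = NUTSDiagnostics(
        divergences=nuts.divergences,
        mean_accept=accept_sum / max(draws, 1),
        step_size=float(eps),
        max_tree_depth_hits=nuts.depth_hits,
    )
    return out, diag
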
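"""Numba kernels for the joint log-density gradients.

The models are small (tens of latents, ~100 observations) so a NUTS run is
dominated by per-call overhead rather than arithmetic; these loop-level
kernels evaluate log-density and gradient in a few microseconds.  Layouts
must match the block layouts constructed in :mod:`lncass.models`; the
finite-difference gradient tests guard that correspondence.

Each kernel writes the gradient into ``grad`` and returns the log density.
"""

import math

import numpy as np
from numba import njit

_LOG2PI = math.log(2.0 * math.pi)
_HALF_LOG_2_OVER_PI = 0.5 * math.log(2.0 / math.pi)


@njit(cache=True)
def _expit(t):
    if t >= 0.0:
        return 1.0 / (1.0 + math.exp(-t))
    e = math.exp(t)
    return e / (1.0 + e)


@njit(cache=True)
def _log1pexp(t):
    # log(1 + exp(t)) without overflow
    if t > 35.0:
        return t
    if t < -35.0:
        return math.exp(t)
    return math.log1p(math.exp(t))


@njit(cache=True)
def _noise_terms(zeta_raw, noise_scale):
    """Half-normal(0, noise_scale) prior on sd = exp(zeta) plus Jacobian.

    Returns (sd, logp_term, dlogp_dzeta); zeta clipped so exp stays finite on
    wild trajectories (that region is divergent regardless).
    """
    zeta = min(max(zeta_raw, -40.0), 40.0)
    sd = math.exp(zeta)
    logp = _HALF_LOG_2_OVER_PI - math.log(noise_scale) - 0.5 * sd * sd / (noise_scale * noise_scale) + zeta
    dz = -sd * sd / (noise_scale * noise_scale) + 1.0
    return sd, logp, dz


@njit(cache=True)
def flat_kernel(
    x, X, y, tau, mu_l, sig_l, intercept_sd, noise_scale,
    gaussian, sample_sigma, freeze_lambda, prior_only, fixed_sd, grad,
):
    n, p = X.shape
    dim = x.shape[0]
    logp = -0.5 * _LOG2PI * dim
    for i in range(dim):
        logp -= 0.5 * x[i] * x[i]
        grad[i] = -x[i]

    pos = 1
    i_sig = -1
    if sample_sigma:
        i_sig = pos
        pos += 1
    u0 = -1
    if not freeze_lambda:
        u0 = pos
        pos += p
    z0 = pos

    sd = fixed_sd
    if sample_sigma:
        sd_, lp_, dz_ = _noise_terms(x[i_sig], noise_scale)
        sd = sd_
        logp += lp_ - (-0.5 * x[i_sig] * x[i_sig] - 0.5 * _LOG2PI)
        grad[i_sig] = dz_

    lam = np.ones(p)
    beta = np.empty(p)
    for j in range(p):
        if not freeze_lambda:
            lam[j] = _expit(mu_l + sig_l * x[u0 + j])
        beta[j] = tau * lam[j] * x[z0 + j]

    if prior_only:
        return logp

    b0 = intercept_sd * x[0]
    dl_deta_sum = 0.0
    c = np.zeros(p)
    if gaussian:
        ss = 0.0
        for i in range(n):
            eta = b0
            for j in range(p):
                eta += X[i, j] * beta[j]
            r = y[i] - eta
            ss += r * r
            d = r / (sd * sd)
            dl_deta_sum += d
            for j in range(p):
                c[j] += X[i, j] * d
        logp += -0.5 * n * _LOG2PI - n * math.log(sd) - 0.5 * ss / (sd * sd)
        if sample_sigma:
            grad[i_sig] += -n + ss / (sd * sd)
    else:
        for i in range(n):
            eta = b0
            for j in range(p):
                eta += X[i, j] * beta[j]
            logp += y[i] * eta - _log1pexp(eta)
            d = y[i] - _expit(eta)
            dl_deta_sum += d
            for j in range(p):
                c[j] += X[i, j] * d

    grad[0] += intercept_sd * dl_deta_sum
    for j in range(p):
        grad[z0 + j] += c[j] * tau * lam[j]
        if not freeze_lambda:
            grad[u0 + j] += c[j] * tau * x[z0 + j] * lam[j] * (1.0 - lam[j]) * sig_l
    return logp


@njit(cache=True)
def grouped_kernel(
    x, X, y, gidx, n_groups, tau, mu_l, sig_l, intercept_sd, noise_scale,
    gaussian, grad,
):
    n, p = X.shape
    G = n_groups
    dim = x.shape[0]
    logp = -0.5 * _LOG2PI * dim
    for i in range(dim):
        logp -= 0.5 * x[i] * x[i]
        grad[i] = -x[i]

    pos = 1
    i_sig = -1
    if gaussian:
        i_sig = pos
        pos += 1
    ug0 = pos
    zg0 = ug0 + G
    um0 = zg0 + G
    w0 = um0 + p

    sd = 1.0
    if gaussian:
        sd_, lp_, dz_ = _noise_terms(x[i_sig], noise_scale)
        sd = sd_
        logp += lp_ - (-0.5 * x[i_sig] * x[i_sig] - 0.5 * _LOG2PI)
        grad[i_sig] = dz_

    lam_g = np.empty(G)
    for g in range(G):
        lam_g[g] = _expit(mu_l + sig_l * x[ug0 + g])
    lam_m = np.empty(p)
    inner = np.empty(p)
    beta = np.empty(p)
    for j in range(p):
        lam_m[j] = _expit(mu_l + sig_l * x[um0 + j])
        g = gidx[j]
        inner[j] = x[zg0 + g] + lam_m[j] * x[w0 + j]
        beta[j] = tau * lam_g[g] * inner[j]

    b0 = intercept_sd * x[0]
    dl_deta_sum = 0.0
    c = np.zeros(p)
    if gaussian:
        ss = 0.0
        for i in range(n):
            eta = b0
            for j in range(p):
                eta += X[i, j] * beta[j]
            r = y[i] - eta
            ss += r * r
            d = r / (sd * sd)
            dl_deta_sum += d
            for j in range(p):
                c[j] += X[i, j] * d
        logp += -0.5 * n * _LOG2PI - n * math.log(sd) - 0.5 * ss / (sd * sd)
        grad[i_sig] += -n + ss / (sd * sd)
    else:
        for i in range(n):
            eta = b0
            for j in range(p):
                eta += X[i, j] * beta[j]
            logp += y[i] * eta - _log1pexp(eta)
            d = y[i] - _expit(eta)
            dl_deta_sum += d
            for j in range(p):
                c[j] += X[i, j] * d

    grad[0] += intercept_sd * dl_deta_sum
    for j in range(p):
        g = gidx[j]
        lg = lam_g[g]
        grad[w0 + j] += c[j] * tau * lg * lam_m[j]
        grad[um0 + j] += c[j] * tau * lg * x[w0 + j] * lam_m[j] * (1.0 - lam_m[j]) * sig_l
        grad[zg0 + g] += c[j] * tau * lg
        grad[ug0 + g] += c[j] * tau * inner[j] * lg * (1.0 - lg) * sig_l
    return logp


@njit(cache=True)
def gam_kernel(x, B, y, n_knots, tau, mu_l, sig_l, intercept_sd, grad):
    """Hierarchical GAM, binomial family.

    ``B`` is the covariate-major basis matrix with 1 + n_knots columns per
    covariate; latent layout: [intercept, u(p), z(p), v(p), w(p*K)] with the
    v/w blocks absent when n_knots == 0.
    """
    n = B.shape[0]
    K = n_knots
    width = 1 + K
    p = B.shape[1] // width
    dim = x.shape[0]
    logp = -0.5 * _LOG2PI * dim
    for i in range(dim):
        logp -= 0.5 * x[i] * x[i]
        grad[i] = -x[i]

    u0 = 1
    z0 = u0 + p
    v0 = z0 + p
    w0 = v0 + p

    lam = np.empty(p)
    lam_nl = np.ones(p)
    coef = np.empty(p * width)
    for j in range(p):
        lam[j] = _expit(mu_l + sig_l * x[u0 + j])
        if K > 0:
            lam_nl[j] = _expit(mu_l + sig_l * x[v0 + j])
        coef[j * width] = tau * lam[j] * x[z0 + j]
        for k in range(K):
            coef[j * width + 1 + k] = tau * lam[j] * lam_nl[j] * x[w0 + j * K + k]

    b0 = intercept_sd * x[0]
    dl_deta_sum = 0.0
    g = np.zeros(p * width)
    for i in range(n):
        eta = b0
        for m in range(p * width):
            eta += B[i, m] * coef[m]
        logp += y[i] * eta - _log1pexp(eta)
        d = y[i] - _expit(eta)
        dl_deta_sum += d
        for m in range(p * width):
            g[m] += B[i, m] * d

    grad[0] += intercept_sd * dl_deta_sum
    for j in range(p):
        g_lin = g[j * width]
        grad[z0 + j] += g_lin * tau * lam[j]
        dlam = g_lin * tau * x[z0 + j]
        if K > 0:
            s_wk = 0.0
            for k in range(K):
                gk = g[j * width + 1 + k]
                wk = x[w0 + j * K + k]
                s_wk += gk * wk
                grad[w0 + j * K + k] += gk * tau * lam[j] * lam_nl[j]
            dlam += s_wk * tau * lam_nl[j]
            grad[v0 + j] += s_wk * tau * lam[j] * lam_nl[j] * (1.0 - lam_nl[j]) * sig_l
        grad[u0 + j] += dlam * lam[j] * (1.0 - lam[j]) * sig_l
    return logp
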
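"""Numba Gibbs-sampler kernel for the Bayes-B marker model.

Kept free of Python objects so the whole chain compiles to machine code;
``Z`` must be Fortran-ordered float64 so column sweeps are contiguous.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def bayesb_gibbs(Z, y, pi, nu, S, nu_e, S_e, n_iter, burn_in, thin, seed):
    """Single-site Gibbs sampler with a point-mass/scaled-inv-chi2 mixture prior.

    Returns posterior means over thinned post-burn-in samples:
    (mu, effects, inclusion probabilities, residual variance, n_samples).
    """
    np.random.seed(seed)
    n, p = Z.shape
    zsq = np.zeros(p)
    for k in range(p):
        acc = 0.0
        for i in range(n):
            acc += Z[i, k] * Z[i, k]
        zsq[k] = acc

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    g = np.zeros(p)
    sigma_g = np.full(p, S)
    e = np.empty(n)
    vy = 0.0
    for i in range(n):
        e[i] = y[i] - mu
        vy += e[i] * e[i]
    sigma_e = max(vy / n * 0.5, 1e-12)

    mu_sum = 0.0
    se_sum = 0.0
    g_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    n_samples = 0

    for it in range(n_iter):
        # intercept
        acc = 0.0
        for i in range(n):
            acc += e[i] + mu
        mean_mu = acc / n
        new_mu = np.random.normal(mean_mu, np.sqrt(sigma_e / n))
        shift = new_mu - mu
        for i in range(n):
            e[i] -= shift
        mu = new_mu

        # marker sweep
        for k in range(p):
            gk = g[k]
            if gk != 0.0:
                for i in range(n):
                    e[i] += Z[i, k] * gk
            c = zsq[k]
            if c <= 0.0:
                g[k] = 0.0
                sigma_g[k] = nu * S / np.random.chisquare(nu)
                continue
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, k] * e[i]
            s2k = sigma_g[k]
            v1 = c * s2k + sigma_e
            logbf = 0.5 * (np.log(sigma_e / v1) + rhs * rhs * s2k / (sigma_e * v1))
            # P(delta=1 | ...) = (1-pi) BF / ((1-pi) BF + pi)
            lo = np.log(1.0 - pi) + logbf - np.log(pi)
            if lo > 35.0:
                p_incl = 1.0
            elif lo < -35.0:
                p_incl = 0.0
            else:
                p_incl = 1.0 / (1.0 + np.exp(-lo))
            if np.random.random() < p_incl:
                prec = c / sigma_e + 1.0 / s2k
                mean_g = (rhs / sigma_e) / prec
                gk_new = np.random.normal(mean_g, np.sqrt(1.0 / prec))
                g[k] = gk_new
                for i in range(n):
                    e[i] -= Z[i, k] * gk_new
                sigma_g[k] = (nu * S + gk_new * gk_new) / np.random.chisquare(nu + 1.0)
            else:
                g[k] = 0.0
                sigma_g[k] = nu * S / np.random.chisquare(nu)

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma_e = (sse + nu_e * S_e) / np.random.chisquare(n + nu_e)
        if sigma_e < 1e-12:
            sigma_e = 1e-12

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_samples += 1
            mu_sum += mu
            se_sum += sigma_e
            for k in range(p):
                g_sum[k] += g[k]
                if g[k] != 0.0:
                    incl_sum[k] += 1.0

    inv = 1.0 / max(n_samples, 1)
    return mu_sum * inv, g_sum * inv, incl_sum * inv, se_sum * inv, n_samples
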
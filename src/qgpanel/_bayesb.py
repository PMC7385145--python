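"""Numba Gibbs-sampler kernel for the BayesB spike-slab regression.

Kept separate from the public prediction API so the jitted function stays a
plain array-in / array-out kernel. Seeding happens inside the jitted code
(numba keeps a per-thread RNG state), which makes a run a pure function of
(y, X, settings, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_bayesb(
    y,
    X,
    n_iter,
    burn_in,
    thin,
    df_beta,
    S_beta,
    pi0,
    p0,
    df_e,
    S_e,
    update_pi,
    update_var,
    update_scale,
    gamma_r,
    gamma_s,
    fixed_sigma2_e,
    seed,
):
    """One BayesB chain; returns posterior means and a failure iteration.

    Marker effects follow the spike-slab prior
    pi * N(0, sigma2_beta_k) + (1 - pi) * delta_0 with marker-specific
    variances sigma2_beta_k ~ scaled-inv-chi2(df_beta, S_beta); pi gets a
    Beta(p0*pi0, p0*(1-pi0)) prior and S_beta optionally a Gamma(r, s)
    prior. The residual variance is scaled-inv-chi2(df_e, S_e) unless fixed.
    """
    np.random.seed(seed)
    n, p = X.shape
    xx = np.empty(p)
    for k in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, k] * X[i, k]
        xx[k] = s

    beta = np.zeros(p)
    sigma2_beta = np.full(p, S_beta)
    pi = pi0
    mu = y.mean()
    e = y - mu
    sigma2_e = fixed_sigma2_e if fixed_sigma2_e > 0 else max(e.var(), 1e-8)
    s_beta_cur = S_beta

    beta_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    mu_sum = 0.0
    sig2e_sum = 0.0
    n_samples = 0

    for it in range(n_iter):
        # intercept
        ebar = 0.0
        for i in range(n):
            ebar += e[i]
        ebar = ebar / n + mu
        new_mu = ebar + np.random.standard_normal() * np.sqrt(sigma2_e / n)
        shift = mu - new_mu
        for i in range(n):
            e[i] += shift
        mu = new_mu

        # marker effects (sequential scan)
        for k in range(p):
            if xx[k] <= 0.0:
                continue
            bk = beta[k]
            rhs = 0.0
            for i in range(n):
                rhs += X[i, k] * e[i]
            rhs += xx[k] * bk
            s2b = sigma2_beta[k]
            v = xx[k] * s2b + sigma2_e
            if pi >= 1.0:
                include = True
            elif pi <= 0.0:
                include = False
            else:
                logratio = (
                    0.5 * np.log(sigma2_e / v)
                    + 0.5 * rhs * rhs * s2b / (sigma2_e * v)
                    + np.log(pi / (1.0 - pi))
                )
                if logratio > 35.0:
                    include = True
                elif logratio < -35.0:
                    include = False
                else:
                    include = np.random.random() < 1.0 / (1.0 + np.exp(-logratio))
            if include:
                post_mean = rhs * s2b / v
                post_sd = np.sqrt(sigma2_e * s2b / v)
                newb = post_mean + np.random.standard_normal() * post_sd
            else:
                newb = 0.0
            if newb != bk:
                diff = bk - newb
                for i in range(n):
                    e[i] += X[i, k] * diff
                beta[k] = newb
            if update_var:
                df_post = df_beta + (1.0 if beta[k] != 0.0 else 0.0)
                ss = beta[k] * beta[k] + df_beta * s_beta_cur
                sigma2_beta[k] = ss / np.random.chisquare(df_post)

        # mixture weight
        if update_pi:
            n_in = 0
            for k in range(p):
                if beta[k] != 0.0:
                    n_in += 1
            a = p0 * pi0 + n_in
            b = p0 * (1.0 - pi0) + (p - n_in)
            pi = np.random.beta(a, b)
            if pi < 1e-6:
                pi = 1e-6
            elif pi > 1.0 - 1e-6:
                pi = 1.0 - 1e-6

        # prior scale of the marker variances
        if update_scale:
            inv_sum = 0.0
            for k in range(p):
                inv_sum += 1.0 / sigma2_beta[k]
            shape = gamma_r + 0.5 * p * df_beta
            rate = gamma_s + 0.5 * df_beta * inv_sum
            s_beta_cur = np.random.gamma(shape, 1.0 / rate)

        # residual variance
        if fixed_sigma2_e <= 0:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            sigma2_e = (sse + df_e * S_e) / np.random.chisquare(n + df_e)

        if not np.isfinite(sigma2_e):
            return beta_sum, incl_sum, mu_sum, sig2e_sum, n_samples, it

        if it >= burn_in and (it - burn_in) % thin == 0:
            for k in range(p):
                beta_sum[k] += beta[k]
                if beta[k] != 0.0:
                    incl_sum[k] += 1.0
            mu_sum += mu
            sig2e_sum += sigma2_e
            n_samples += 1

    return beta_sum, incl_sum, mu_sum, sig2e_sum, n_samples, -1
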
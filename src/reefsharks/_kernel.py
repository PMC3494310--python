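"""Compiled Metropolis-within-Gibbs kernel for the hierarchical count model.

The sampler updates, in order: the intercept, each regression coefficient,
each latent inclusion indicator (when selection is on), each island mean
density, the hypervariance, and the negative-binomial overdispersion.  All
scalar updates are random-walk Metropolis (log-scale walks for the two
positive scale parameters, with the Jacobian included); a coefficient whose
indicator is currently 0 is refreshed directly from its prior, which is its
full conditional under the indicator parameterization.  Step sizes adapt
toward a 0.44 acceptance rate during burn-in only, so the post-burn-in
chain is a fixed Markov kernel with the correct invariant distribution.

Likelihood bookkeeping is incremental: island-mean updates touch only that
island's tows and cancel the count-dependent gamma terms analytically;
coefficient, indicator and hypervariance updates touch only the island-level
truncated-normal terms; only the overdispersion update scans every tow.
"""

import math

import numpy as np
from numba import njit

_LOG_SQRT_2PI = 0.9189385332046727
_INV_SQRT2 = 0.7071067811865476


@njit(cache=True)
def _log_ndtr(z):
    """log of the standard normal CDF, stable far into the lower tail."""
    if z > -8.0:
        return math.log(0.5 * math.erfc(-z * _INV_SQRT2))
    zi = 1.0 / (z * z)
    return -0.5 * z * z - math.log(-z) - _LOG_SQRT_2PI + math.log1p(-zi + 3.0 * zi * zi)


@njit(cache=True)
def _tn_lp(mu, loc, var):
    """log-density of a normal(loc, var) truncated to (0, inf)."""
    if mu <= 0.0:
        return -np.inf
    s = math.sqrt(var)
    z = (mu - loc) / s
    return -0.5 * z * z - math.log(s) - _LOG_SQRT_2PI - _log_ndtr(loc / s)


@njit(cache=True)
def _tn_sum(mu, E, sigma2, n_per, link):
    tot = 0.0
    for i in range(E.shape[0]):
        loc = math.exp(E[i]) if link == 1 else E[i]
        tot += _tn_lp(mu[i], loc, sigma2 / n_per[i])
    return tot


@njit(cache=True)
def run_chain(
    y,
    area,
    isl_start,
    n_per,
    X,
    link,
    selection,
    coef_mean,
    coef_var,
    sv_shape,
    sv_rate,
    sv_on_prec,
    k_shape,
    k_rate,
    w_prob,
    n_iter,
    n_burn,
    seed,
    fix_sigma2,
    fix_k,
    alpha0,
    beta0,
    mu0,
    sigma2_0,
    k0,
    w0,
    out_alpha,
    out_beta,
    out_mu,
    out_sigma2,
    out_k,
    out_w,
    acc,
):
    np.random.seed(seed)
    I = n_per.shape[0]
    P = X.shape[1]

    alpha = alpha0
    beta = beta0.copy()
    mu = mu0.copy()
    sigma2 = sigma2_0
    k = k0
    w = w0.copy()

    if fix_sigma2 > 0.0:
        sigma2 = fix_sigma2
    if fix_k > 0.0:
        k = fix_k

    E = np.empty(I)
    for i in range(I):
        e = alpha
        for j in range(P):
            if w[j] == 1:
                e += beta[j] * X[i, j]
        E[i] = e

    # per-island count totals; gamma terms in the NB pmf that depend only on
    # y and k cancel in island-mean updates, leaving 2 logs per tow
    ysum = np.zeros(I)
    for i in range(I):
        for t in range(isl_start[i], isl_start[i + 1]):
            ysum[i] += y[t]
    T = y.shape[0]
    coef_sd = math.sqrt(coef_var)
    logit_w = math.log(w_prob) - math.log(1.0 - w_prob)

    s_alpha = 0.1
    s_beta = np.full(P, 0.2)
    s_mu = np.full(I, 0.3)
    s_ls2 = 0.5
    s_lk = 0.4

    # adaptation-window and post-burn-in acceptance counters
    WIN = 50
    aw_alpha = 0
    aw_beta = np.zeros(P, dtype=np.int64)
    pw_beta = np.zeros(P, dtype=np.int64)
    aw_mu = np.zeros(I, dtype=np.int64)
    aw_s2 = 0
    aw_k = 0
    n_alpha = 0
    n_beta = 0
    n_mu = 0
    n_s2 = 0
    n_k = 0

    for it in range(n_iter):
        # --- intercept ---
        d = s_alpha * np.random.normal()
        delta = (
            _tn_sum(mu, E + d, sigma2, n_per, link)
            - _tn_sum(mu, E, sigma2, n_per, link)
            - ((alpha + d - coef_mean) ** 2 - (alpha - coef_mean) ** 2)
            / (2.0 * coef_var)
        )
        if math.log(np.random.random()) < delta:
            alpha += d
            for i in range(I):
                E[i] += d
            aw_alpha += 1
            if it >= n_burn:
                n_alpha += 1

        # --- coefficients ---
        for j in range(P):
            if selection == 1 and w[j] == 0:
                # conditional is the prior when the effect is gated off
                beta[j] = coef_mean + coef_sd * np.random.normal()
                continue
            pw_beta[j] += 1
            d = s_beta[j] * np.random.normal()
            Ep = E + d * X[:, j]
            delta = (
                _tn_sum(mu, Ep, sigma2, n_per, link)
                - _tn_sum(mu, E, sigma2, n_per, link)
                - ((beta[j] + d - coef_mean) ** 2 - (beta[j] - coef_mean) ** 2)
                / (2.0 * coef_var)
            )
            if math.log(np.random.random()) < delta:
                beta[j] += d
                E = Ep
                aw_beta[j] += 1
                if it >= n_burn:
                    n_beta += 1

        # --- inclusion indicators (Bernoulli-Metropolis flips) ---
        if selection == 1:
            for j in range(P):
                sign = -1.0 if w[j] == 1 else 1.0
                Ep = E + sign * beta[j] * X[:, j]
                delta = (
                    _tn_sum(mu, Ep, sigma2, n_per, link)
                    - _tn_sum(mu, E, sigma2, n_per, link)
                    + sign * logit_w
                )
                if math.log(np.random.random()) < delta:
                    w[j] = 1 - w[j]
                    E = Ep

        # --- island mean densities ---
        for i in range(I):
            prop = mu[i] + s_mu[i] * np.random.normal()
            if prop <= 0.0:
                continue
            loc = math.exp(E[i]) if link == 1 else E[i]
            var_i = sigma2 / n_per[i]
            delta = ysum[i] * math.log(prop / mu[i])
            for t in range(isl_start[i], isl_start[i + 1]):
                delta += (k + y[t]) * (
                    math.log(k + mu[i] * area[t]) - math.log(k + prop * area[t])
                )
            delta += _tn_lp(prop, loc, var_i) - _tn_lp(mu[i], loc, var_i)
            if math.log(np.random.random()) < delta:
                mu[i] = prop
                aw_mu[i] += 1
                if it >= n_burn:
                    n_mu += 1

        # --- hypervariance (log-scale walk) ---
        if fix_sigma2 <= 0.0:
            s2p = sigma2 * math.exp(s_ls2 * np.random.normal())
            if sv_on_prec == 1:
                pr = -(sv_shape + 1.0) * (math.log(s2p) - math.log(sigma2)) - sv_rate * (
                    1.0 / s2p - 1.0 / sigma2
                )
            else:
                pr = (sv_shape - 1.0) * (math.log(s2p) - math.log(sigma2)) - sv_rate * (
                    s2p - sigma2
                )
            delta = (
                _tn_sum(mu, E, s2p, n_per, link)
                - _tn_sum(mu, E, sigma2, n_per, link)
                + pr
                + math.log(s2p)
                - math.log(sigma2)
            )
            if math.log(np.random.random()) < delta:
                sigma2 = s2p
                aw_s2 += 1
                if it >= n_burn:
                    n_s2 += 1

        # --- overdispersion (log-scale walk, full count scan) ---
        if fix_k <= 0.0:
            kp = k * math.exp(s_lk * np.random.normal())
            delta = T * (kp * math.log(kp) - k * math.log(k)) - T * (
                math.lgamma(kp) - math.lgamma(k)
            )
            for i in range(I):
                for t in range(isl_start[i], isl_start[i + 1]):
                    lam = mu[i] * area[t]
                    delta += (
                        math.lgamma(y[t] + kp)
                        - math.lgamma(y[t] + k)
                        - (kp + y[t]) * math.log(kp + lam)
                        + (k + y[t]) * math.log(k + lam)
                    )
            delta += (
                (k_shape - 1.0) * (math.log(kp) - math.log(k))
                - k_rate * (kp - k)
                + math.log(kp)
                - math.log(k)
            )
            if math.log(np.random.random()) < delta:
                k = kp
                aw_k += 1
                if it >= n_burn:
                    n_k += 1

        # --- step-size adaptation, burn-in only ---
        if it < n_burn and (it + 1) % WIN == 0:
            s_alpha *= math.exp(0.6 * (aw_alpha / WIN - 0.44))
            aw_alpha = 0
            for j in range(P):
                if pw_beta[j] > 0:
                    s_beta[j] *= math.exp(0.6 * (aw_beta[j] / pw_beta[j] - 0.44))
                aw_beta[j] = 0
                pw_beta[j] = 0
            for i in range(I):
                s_mu[i] *= math.exp(0.6 * (aw_mu[i] / WIN - 0.44))
                aw_mu[i] = 0
            s_ls2 *= math.exp(0.6 * (aw_s2 / WIN - 0.44))
            aw_s2 = 0
            s_lk *= math.exp(0.6 * (aw_k / WIN - 0.44))
            aw_k = 0

        if it >= n_burn:
            r = it - n_burn
            out_alpha[r] = alpha
            out_sigma2[r] = sigma2
            out_k[r] = k
            for j in range(P):
                out_beta[r, j] = beta[j]
                out_w[r, j] = w[j]
            for i in range(I):
                out_mu[r, i] = mu[i]

    keep = max(n_iter - n_burn, 1)
    acc[0] = n_alpha / keep
    acc[1] = n_beta / (keep * max(P, 1))
    acc[2] = n_mu / (keep * I)
    acc[3] = n_s2 / keep
    acc[4] = n_k / keep
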
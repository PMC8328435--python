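"""JIT-compiled log-posterior and adaptive Metropolis chain runner.

This mirrors :mod:`eider_ipm.model` exactly (same densities, same additive
constants); a test asserts equality against the readable reference path.
The sampler is componentwise random-walk Metropolis with Robbins-Monro
scale adaptation during warm-up, targeting ~0.44 acceptance.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG_2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _logit_beta_lpdf(x, a, b):
    """log density of logit-transformed Beta(a, b) variable (with Jacobian)."""
    m = 1.0 / (1.0 + math.exp(-x))
    if m <= 0.0 or m >= 1.0:
        return -np.inf
    norm = math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
    return norm + (a - 1.0) * math.log(m) + (b - 1.0) * math.log(1.0 - m) + math.log(
        m * (1.0 - m)
    )


@njit(cache=True)
def logpost(
    theta,
    T,
    ice,
    ao,
    fox,
    precip,
    y,
    sig_y,
    y_obs,
    Ra,
    ma,
    nevera,
    Rd,
    md,
    neverd,
    nn,
    nsucc,
    clutch_sum,
    clutch_n,
    clutch_lgam,
    beta_priors,
    cs_prior,
    sigma_bounds,
    beta_sd,
    n0_bounds,
    ds,
):
    """Log posterior kernel of the flat parameter vector ``theta``."""
    # ---- unpack ------------------------------------------------------
    mu_a, sig_a = theta[0], theta[1]
    mu_j, sig_j = theta[2], theta[3]
    l_alpha = theta[4]
    mu_ns, sig_ns = theta[5], theta[6]
    mu_p, sig_p = theta[7], theta[8]
    log_cs = theta[9]
    betas = theta[10:17]
    n0 = theta[17:21]
    o = 21
    eps_a = theta[o : o + T - 1]
    o += T - 1
    eps_j = theta[o : o + T - 1]
    o += T - 1
    eps_ns = theta[o : o + T]
    o += T
    eps_p = theta[o : o + T - 1]

    # ---- priors ------------------------------------------------------
    lp = 0.0
    lp += _logit_beta_lpdf(mu_a, beta_priors[0, 0], beta_priors[0, 1])
    lp += _logit_beta_lpdf(mu_j, beta_priors[1, 0], beta_priors[1, 1])
    lp += _logit_beta_lpdf(l_alpha, beta_priors[2, 0], beta_priors[2, 1])
    lp += _logit_beta_lpdf(mu_ns, beta_priors[3, 0], beta_priors[3, 1])
    lp += _logit_beta_lpdf(mu_p, beta_priors[4, 0], beta_priors[4, 1])
    cs = math.exp(log_cs)
    a_cs, b_cs = cs_prior[0], cs_prior[1]
    lp += (
        a_cs * math.log(b_cs)
        - math.lgamma(a_cs)
        + (a_cs - 1.0) * log_cs
        - b_cs * cs
        + log_cs
    )
    slo, shi = sigma_bounds[0], sigma_bounds[1]
    for s in (sig_a, sig_j, sig_ns, sig_p):
        if s < slo or s > shi:
            return -np.inf
        lp += -math.log(shi - slo)
    for k in range(7):
        lp += -0.5 * LOG_2PI - math.log(beta_sd) - 0.5 * (betas[k] / beta_sd) ** 2
    for k in range(4):
        if n0[k] < n0_bounds[k, 0] or n0[k] > n0_bounds[k, 1]:
            return -np.inf
        lp += -math.log(n0_bounds[k, 1] - n0_bounds[k, 0])
    for k in range(T - 1):
        lp += -0.5 * LOG_2PI - math.log(sig_a) - 0.5 * (eps_a[k] / sig_a) ** 2
        lp += -0.5 * LOG_2PI - math.log(sig_j) - 0.5 * (eps_j[k] / sig_j) ** 2
        lp += -0.5 * LOG_2PI - math.log(sig_p) - 0.5 * (eps_p[k] / sig_p) ** 2
    for k in range(T):
        lp += -0.5 * LOG_2PI - math.log(sig_ns) - 0.5 * (eps_ns[k] / sig_ns) ** 2
    if not np.isfinite(lp):
        return -np.inf

    # ---- annual rates ------------------------------------------------
    alpha = 1.0 / (1.0 + math.exp(-l_alpha))
    phi_a = np.empty(T - 1)
    phi_j = np.empty(T - 1)
    p = np.empty(T - 1)
    for k in range(T - 1):
        xa = mu_a + betas[0] * ice[k + 1] + betas[1] * ice[k + 1] ** 2 + eps_a[k]
        phi_a[k] = 1.0 / (1.0 + math.exp(-xa))
        xj = mu_j + betas[2] * ao[k + 1] + eps_j[k]
        phi_j[k] = 1.0 / (1.0 + math.exp(-xj))
        p[k] = 1.0 / (1.0 + math.exp(-(mu_p + eps_p[k])))
    ns = np.empty(T)
    for k in range(T):
        xn = (
            mu_ns
            + betas[3] * ice[k]
            + betas[4] * ice[k] ** 2
            + betas[5] * fox[k]
            + betas[6] * precip[k]
            + eps_ns[k]
        )
        ns[k] = 1.0 / (1.0 + math.exp(-xn))

    # ---- latent stages and count likelihood --------------------------
    n1, n2, n3, n4 = n0[0], n0[1], n0[2], n0[3]
    ll = 0.0
    for k in range(T):
        if y_obs[k]:
            z = (y[k] - 2.0 * (n3 + n4)) / sig_y[k]
            ll += -0.5 * LOG_2PI - math.log(sig_y[k]) - 0.5 * z * z
        if k < T - 1:
            fec = ns[k] * cs * ds
            n1n = 0.5 * fec * phi_j[k] * (n3 + n4)
            n2n = phi_a[k] * (1.0 - alpha) * n1
            n3n = phi_a[k] * alpha * n1
            n4n = phi_a[k] * (n2 + n3 + n4)
            n1, n2, n3, n4 = n1n, n2n, n3n, n4n

    # ---- adult m-array -----------------------------------------------
    for t in range(T - 1):
        if Ra[t] == 0 and Rd[t] == 0:
            continue
        if Ra[t] > 0:
            alive = 1.0
            rowsum = 0.0
            for j in range(t + 1, T):
                cell = alive * phi_a[j - 1] * p[j - 1]
                rowsum += cell
                if ma[t, j] > 0:
                    if cell <= 0.0:
                        return -np.inf
                    ll += ma[t, j] * math.log(cell)
                alive *= phi_a[j - 1] * (1.0 - p[j - 1])
            if nevera[t] > 0:
                nv = 1.0 - rowsum
                if nv <= 0.0:
                    return -np.inf
                ll += nevera[t] * math.log(nv)
        # ---- duckling m-array ----
        if Rd[t] > 0:
            rowsum = 0.0
            if t + 2 < T:
                reach2 = phi_j[t] * phi_a[t + 1]
                cell = reach2 * alpha * p[t + 1]
                rowsum += cell
                if md[t, t + 2] > 0:
                    if cell <= 0.0:
                        return -np.inf
                    ll += md[t, t + 2] * math.log(cell)
                alive = reach2 * (1.0 - alpha * p[t + 1])
                for j in range(t + 3, T):
                    cell = alive * phi_a[j - 1] * p[j - 1]
                    rowsum += cell
                    if md[t, j] > 0:
                        if cell <= 0.0:
                            return -np.inf
                        ll += md[t, j] * math.log(cell)
                    alive *= phi_a[j - 1] * (1.0 - p[j - 1])
            if neverd[t] > 0:
                nv = 1.0 - rowsum
                if nv <= 0.0:
                    return -np.inf
                ll += neverd[t] * math.log(nv)

    # ---- productivity ------------------------------------------------
    for k in range(T):
        if nn[k] > 0:
            pk = ns[k]
            lcomb = (
                math.lgamma(nn[k] + 1.0)
                - math.lgamma(nsucc[k] + 1.0)
                - math.lgamma(nn[k] - nsucc[k] + 1.0)
            )
            if nsucc[k] > 0:
                if pk <= 0.0:
                    return -np.inf
                lcomb += nsucc[k] * math.log(pk)
            if nn[k] - nsucc[k] > 0:
                if pk >= 1.0:
                    return -np.inf
                lcomb += (nn[k] - nsucc[k]) * math.log(1.0 - pk)
            ll += lcomb
    ll += clutch_sum * log_cs - clutch_n * cs - clutch_lgam

    return lp + ll


@njit(cache=True)
def run_chain(
    theta0,
    active,
    n_adapt,
    n_keep,
    thin,
    seed,
    init_step,
    T,
    ice,
    ao,
    fox,
    precip,
    y,
    sig_y,
    y_obs,
    Ra,
    ma,
    nevera,
    Rd,
    md,
    neverd,
    nn,
    nsucc,
    clutch_sum,
    clutch_n,
    clutch_lgam,
    beta_priors,
    cs_prior,
    sigma_bounds,
    beta_sd,
    n0_bounds,
    ds,
):
    """One chain of componentwise adaptive random-walk Metropolis.

    Returns (kept draws, final log-step-sizes, acceptance rate over the
    sampling phase).
    """
    np.random.seed(seed)
    npar = theta0.size
    theta = theta0.copy()
    lstep = np.full(npar, math.log(init_step))
    # Ridge moves: shifting a mean (or a covariate coefficient) while
    # counter-shifting its annual random effects by the matching covariate
    # column leaves every rate -- hence the likelihood -- unchanged, so
    # these moves walk the flat directions of the posterior that defeat
    # componentwise updates.  Moves: 4 means, then the 7 coefficients.
    s_a = 21
    s_j = 21 + (T - 1)
    s_ns = 21 + 2 * (T - 1)
    s_p = 21 + 2 * (T - 1) + T
    n_moves = 11
    mv_idx = np.array([0, 2, 5, 7, 10, 11, 12, 13, 14, 15, 16], dtype=np.int64)
    mv_start = np.array(
        [s_a, s_j, s_ns, s_p, s_a, s_a, s_j, s_ns, s_ns, s_ns, s_ns], dtype=np.int64
    )
    mv_len = np.array(
        [T - 1, T - 1, T, T - 1, T - 1, T - 1, T - 1, T, T, T, T], dtype=np.int64
    )
    mv_col = np.ones((n_moves, T))
    for k in range(T - 1):
        mv_col[4, k] = ice[k + 1]
        mv_col[5, k] = ice[k + 1] * ice[k + 1]
        mv_col[6, k] = ao[k + 1]
    for k in range(T):
        mv_col[7, k] = ice[k]
        mv_col[8, k] = ice[k] * ice[k]
        mv_col[9, k] = fox[k]
        mv_col[10, k] = precip[k]
    mv_on = np.zeros(n_moves, dtype=np.bool_)
    for m in range(n_moves):
        for a_i in range(active.size):
            if active[a_i] == mv_idx[m]:
                mv_on[m] = True
                break
    ltr = np.full(n_moves, math.log(0.2))
    # Scale moves for the sigma/eps funnels: multiply a random-effect SD and
    # its whole eps vector by a common factor (log-normal proposal with the
    # c^(len+1) Jacobian), traversing the funnel that defeats single-site
    # updates when the effects are weakly informed.
    sc_sig = np.array([1, 3, 6, 8], dtype=np.int64)
    sc_start = np.array([s_a, s_j, s_ns, s_p], dtype=np.int64)
    sc_len = np.array([T - 1, T - 1, T, T - 1], dtype=np.int64)
    lsc = np.full(4, math.log(0.2))
    lp = logpost(
        theta, T, ice, ao, fox, precip, y, sig_y, y_obs, Ra, ma, nevera, Rd, md,
        neverd, nn, nsucc, clutch_sum, clutch_n, clutch_lgam, beta_priors,
        cs_prior, sigma_bounds, beta_sd, n0_bounds, ds,
    )
    draws = np.empty((n_keep, npar))
    lps = np.empty(n_keep)
    n_total = n_adapt + n_keep * thin
    acc = 0
    tries = 0
    kept = 0
    for it in range(n_total):
        adapting = it < n_adapt
        gamma = 1.0 / (1.0 + it) ** 0.6 if adapting else 0.0
        for idx in range(active.size):
            i = active[idx]
            old = theta[i]
            theta[i] = old + math.exp(lstep[i]) * np.random.normal()
            lp_new = logpost(
                theta, T, ice, ao, fox, precip, y, sig_y, y_obs, Ra, ma, nevera,
                Rd, md, neverd, nn, nsucc, clutch_sum, clutch_n, clutch_lgam,
                beta_priors, cs_prior, sigma_bounds, beta_sd, n0_bounds, ds,
            )
            dlp = lp_new - lp
            a_prob = math.exp(dlp) if dlp < 0.0 else 1.0
            if np.random.random() < a_prob:
                lp = lp_new
                if not adapting:
                    acc += 1
            else:
                theta[i] = old
            if not adapting:
                tries += 1
            if adapting:
                lstep[i] += gamma * (a_prob - 0.44)
                if lstep[i] < -15.0:
                    lstep[i] = -15.0
                elif lstep[i] > 5.0:
                    lstep[i] = 5.0
        for f in range(n_moves):
            if not mv_on[f]:
                continue
            delta = math.exp(ltr[f]) * np.random.normal()
            theta[mv_idx[f]] += delta
            for k in range(mv_len[f]):
                theta[mv_start[f] + k] -= delta * mv_col[f, k]
            lp_new = logpost(
                theta, T, ice, ao, fox, precip, y, sig_y, y_obs, Ra, ma, nevera,
                Rd, md, neverd, nn, nsucc, clutch_sum, clutch_n, clutch_lgam,
                beta_priors, cs_prior, sigma_bounds, beta_sd, n0_bounds, ds,
            )
            dlp = lp_new - lp
            a_prob = math.exp(dlp) if dlp < 0.0 else 1.0
            if np.random.random() < a_prob:
                lp = lp_new
            else:
                theta[mv_idx[f]] -= delta
                for k in range(mv_len[f]):
                    theta[mv_start[f] + k] += delta * mv_col[f, k]
            if adapting:
                ltr[f] += gamma * (a_prob - 0.44)
                if ltr[f] < -15.0:
                    ltr[f] = -15.0
                elif ltr[f] > 5.0:
                    ltr[f] = 5.0
        for f in range(4):
            logc = math.exp(lsc[f]) * np.random.normal()
            c = math.exp(logc)
            theta[sc_sig[f]] *= c
            for k in range(sc_len[f]):
                theta[sc_start[f] + k] *= c
            lp_new = logpost(
                theta, T, ice, ao, fox, precip, y, sig_y, y_obs, Ra, ma, nevera,
                Rd, md, neverd, nn, nsucc, clutch_sum, clutch_n, clutch_lgam,
                beta_priors, cs_prior, sigma_bounds, beta_sd, n0_bounds, ds,
            )
            dlp = lp_new - lp + (sc_len[f] + 1.0) * logc
            a_prob = math.exp(dlp) if dlp < 0.0 else 1.0
            if np.random.random() < a_prob:
                lp = lp_new
            else:
                theta[sc_sig[f]] /= c
                for k in range(sc_len[f]):
                    theta[sc_start[f] + k] /= c
            if adapting:
                lsc[f] += gamma * (a_prob - 0.44)
                if lsc[f] < -15.0:
                    lsc[f] = -15.0
                elif lsc[f] > 5.0:
                    lsc[f] = 5.0
        if not adapting and (it - n_adapt + 1) % thin == 0:
            draws[kept] = theta
            lps[kept] = lp
            kept += 1
    rate = acc / tries if tries > 0 else 0.0
    return draws, lps, lstep, rate
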
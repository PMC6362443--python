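"""Numba kernels for the Metropolis-within-Gibbs sampler.

One chain = one call to ``run_chain``.  Continuous parameters move by
adaptive scalar random-walk Metropolis (proposal scales tuned during
burn-in only, frozen after), the latent abundance components (N1, S, G)
by +-1 integer proposals plus an S/G exchange move at fixed N, binary
inclusion indicators by Gibbs draws from their full conditionals, and the
CJS alive matrix is marginalized out of all parameter updates by the
forward algorithm (it is re-sampled exactly, via death-time enumeration,
only when a saved draw needs it for the goodness-of-fit discrepancy).

Parameter vector layout (offsets exported as module constants):
a0 a1 a2 a3 | b0..b4 | c0..c4 | d0 d1 | e0 e1 | sigma_a sigma_d |
a4[0..R-1] | d2[0..O-1].
"""

import math

import numpy as np
from numba import njit

# ---- fixed layout ----------------------------------------------------------
IA0, IA1, IA2, IA3 = 0, 1, 2, 3
IB0, IB1, IB2, IB3, IB4 = 4, 5, 6, 7, 8
IC0, IC1, IC2, IC3, IC4 = 9, 10, 11, 12, 13
ID0, ID1 = 14, 15
IE0, IE1 = 16, 17
ISA, ISD = 18, 19
NFIXED = 20          # a4 starts here, d2 at NFIXED + n_transects

# indicator slots
VA1, VA2, VA3, VA4 = 0, 1, 2, 3
VB1, VB2, VB3, VB4 = 4, 5, 6, 7
VC1, VC2, VC3, VC4 = 8, 9, 10, 11
VD1, VD2, VE1 = 12, 13, 14
NV = 15

NEG_INF = -1.0e308


@njit(cache=True)
def _softplus(x):
    if x > 30.0:
        return x
    return math.log1p(math.exp(x))


@njit(cache=True)
def _lpois(n, mu):
    return n * math.log(mu) - mu - math.lgamma(n + 1.0)


@njit(cache=True)
def _lbinom(s, n, p):
    if s < 0 or s > n:
        return NEG_INF
    out = math.lgamma(n + 1.0) - math.lgamma(s + 1.0) - math.lgamma(n - s + 1.0)
    if s > 0:
        out += s * math.log(p)
    if n - s > 0:
        out += (n - s) * math.log1p(-p)
    return out


# ---- predictor arrays ------------------------------------------------------

@njit(cache=True)
def _calc_lam(out, theta, v, dnbr, nboxc, tfire0, transect):
    a1 = theta[IA1] * v[VA1]
    a2 = theta[IA2] * v[VA2]
    a3 = theta[IA3] * v[VA3]
    va4 = v[VA4]
    for j in range(out.shape[0]):
        lp = (theta[IA0] + a1 * dnbr[j] + a2 * nboxc[j] + a3 * tfire0[j]
              + va4 * theta[NFIXED + transect[j]])
        out[j] = math.exp(lp)


@njit(cache=True)
def _calc_phi(out, theta, v, nboxc, tfire, snag, live):
    b1 = theta[IB1] * v[VB1]
    b2 = theta[IB2] * v[VB2]
    b3 = theta[IB3] * v[VB3]
    b4 = theta[IB4] * v[VB4]
    J, T = out.shape
    for j in range(J):
        for t in range(1, T):
            lp = (theta[IB0] + b1 * nboxc[j] + b2 * tfire[j, t]
                  + b3 * live[j, t] + b4 * snag[j, t])
            out[j, t] = 1.0 / (1.0 + math.exp(-lp))


@njit(cache=True)
def _calc_gam(out, theta, v, nboxc, tfire, snag, live):
    c1 = theta[IC1] * v[VC1]
    c2 = theta[IC2] * v[VC2]
    c3 = theta[IC3] * v[VC3]
    c4 = theta[IC4] * v[VC4]
    J, T = out.shape
    for j in range(J):
        for t in range(1, T):
            lp = (theta[IC0] + c1 * nboxc[j] + c2 * tfire[j, t]
                  + c3 * live[j, t] + c4 * snag[j, t])
            out[j, t] = math.exp(lp)


@njit(cache=True)
def _calc_log1mp(out, theta, v, nboxc, obs_assign, id2, tab):
    # p_jkt depends only on (nbox_j, observer): tabulate the distinct values
    d1 = theta[ID1] * v[VD1]
    vd2 = v[VD2]
    n_obs = tab.shape[1]
    for b in range(2):
        for o in range(n_obs):
            tab[b, o] = -_softplus(theta[ID0] + d1 * b + vd2 * theta[id2 + o])
    J, K, T = out.shape
    for j in range(J):
        b = 1 if nboxc[j] > 0.5 else 0
        for k in range(K):
            for t in range(T):
                out[j, k, t] = tab[b, obs_assign[j, k, t]]


# ---- component log-likelihoods --------------------------------------------

@njit(cache=True)
def _ll_lam(lam, N):
    tot = 0.0
    for j in range(lam.shape[0]):
        tot += _lpois(N[j, 0], lam[j])
    return tot


@njit(cache=True)
def _ll_surv(phi, N, S):
    J, T = N.shape
    tot = 0.0
    for j in range(J):
        for t in range(1, T):
            lb = _lbinom(S[j, t], N[j, t - 1], phi[j, t])
            if lb <= NEG_INF:
                return NEG_INF
            tot += lb
    return tot


@njit(cache=True)
def _ll_rec(gam, G):
    J, T = G.shape
    tot = 0.0
    for j in range(J):
        for t in range(1, T):
            tot += _lpois(G[j, t], gam[j, t])
    return tot


@njit(cache=True)
def _obs_cell_ll(yP, sampled, log1mp, j, t, n):
    tot = 0.0
    for k in range(yP.shape[1]):
        if not sampled[j, k, t]:
            continue
        if yP[j, k, t] == 1:
            if n == 0:
                return NEG_INF
            tot += math.log(-math.expm1(n * log1mp[j, k, t]))
        else:
            tot += n * log1mp[j, k, t]
    return tot


@njit(cache=True)
def _ll_obsP(yP, sampled, log1mp, N):
    J = yP.shape[0]
    T = yP.shape[2]
    tot = 0.0
    for j in range(J):
        for t in range(T):
            c = _obs_cell_ll(yP, sampled, log1mp, j, t, N[j, t])
            if c <= NEG_INF:
                return NEG_INF
            tot += c
    return tot


@njit(cache=True)
def _ll_cjs(yB, f_i, site_i, sex_i, phi, e0, e1eff):
    I, T = yB.shape
    tot = 0.0
    for i in range(I):
        fi = f_i[i]
        if fi >= T - 1:
            continue
        pB = 1.0 / (1.0 + math.exp(-(e0 + e1eff * sex_i[i])))
        j = site_i[i]
        alive = 1.0
        dead = 0.0
        for t in range(fi + 1, T):
            ph = phi[j, t]
            if yB[i, t] == 1:
                alive = alive * ph * pB
                dead = 0.0
            else:
                dead = dead + alive * (1.0 - ph)
                alive = alive * ph * (1.0 - pB)
        s = alive + dead
        if s <= 0.0:
            return NEG_INF
        tot += math.log(s)
    return tot



@njit(cache=True)
def _ll_lam_red(lam, N):
    # Poisson terms without lgamma(N+1): constant during parameter moves
    tot = 0.0
    for j in range(lam.shape[0]):
        tot += N[j, 0] * math.log(lam[j]) - lam[j]
    return tot


@njit(cache=True)
def _ll_surv_red(phi, N, S):
    # binomial terms without the binomial coefficient
    J, T = N.shape
    tot = 0.0
    for j in range(J):
        for t in range(1, T):
            s = S[j, t]
            n = N[j, t - 1]
            if s > n:
                return NEG_INF
            p = phi[j, t]
            if s > 0:
                tot += s * math.log(p)
            if n - s > 0:
                tot += (n - s) * math.log1p(-p)
    return tot


@njit(cache=True)
def _ll_rec_red(gam, G):
    # Poisson terms without lgamma(G+1)
    J, T = G.shape
    tot = 0.0
    for j in range(J):
        for t in range(1, T):
            tot += G[j, t] * math.log(gam[j, t]) - gam[j, t]
    return tot



@njit(cache=True)
def _d_obs_incr(yP, sampled, log1mp, j, t, n_old, n_new):
    # change in the observation loglik of cell (j, t) when N moves
    tot = 0.0
    for k in range(yP.shape[1]):
        if not sampled[j, k, t]:
            continue
        l = log1mp[j, k, t]
        if yP[j, k, t] == 1:
            if n_new == 0:
                return NEG_INF
            tot += (math.log(-math.expm1(n_new * l))
                    - math.log(-math.expm1(n_old * l)))
        else:
            tot += (n_new - n_old) * l
    return tot


@njit(cache=True)
def _d_pois(x_old, x_new, mu):
    # log Pois(x_new; mu) - log Pois(x_old; mu) for x_new = x_old +- 1
    if x_new > x_old:
        return math.log(mu) - math.log(x_old + 1.0)
    return math.log(float(x_old)) - math.log(mu)


@njit(cache=True)
def _d_bin_s(s_old, s_new, n, p):
    # success-count move at fixed trials; caller guarantees 0<=s_new<=n
    if s_new > s_old:
        return (math.log(n - s_old) - math.log(s_old + 1.0)
                + math.log(p) - math.log1p(-p))
    return (math.log(float(s_old)) - math.log(n - s_old + 1.0)
            - math.log(p) + math.log1p(-p))


@njit(cache=True)
def _d_bin_n(s, n_old, n_new, p):
    # trial-count move at fixed successes; caller guarantees s<=n_new
    if n_new > n_old:
        return (math.log(n_old + 1.0) - math.log(n_old + 1.0 - s)
                + math.log1p(-p))
    return math.log(float(n_old - s)) - math.log(float(n_old)) - math.log1p(-p)


# ---- priors ----------------------------------------------------------------
# prior_kind: 0 normal(mean, sd); 1 uniform(lo, hi); 2 uniform on ilogit(x);
#             3 normal(0, theta[ISA]); 4 normal(0, theta[ISD])

@njit(cache=True)
def _lprior(idx, x, theta, prior_kind, prior_mean, prior_sd, unif_lo, unif_hi):
    k = prior_kind[idx]
    if k == 0:
        z = (x - prior_mean[idx]) / prior_sd[idx]
        return -0.5 * z * z
    if k == 1:
        if unif_lo[idx] <= x <= unif_hi[idx]:
            return 0.0
        return NEG_INF
    if k == 2:
        # flat on the probability scale: log|d ilogit/dx|
        return -_softplus(x) - _softplus(-x)
    if k == 3:
        z = x / theta[ISA]
        return -0.5 * z * z
    z = x / theta[ISD]
    return -0.5 * z * z


# ---- GOF helpers -----------------------------------------------------------

@njit(cache=True)
def _gof_point(yP, sampled, log1mp, N):
    t_obs = 0.0
    t_rep = 0.0
    J, K, T = yP.shape
    for j in range(J):
        for t in range(T):
            n = N[j, t]
            for k in range(K):
                if not sampled[j, k, t]:
                    continue
                pi = -math.expm1(n * log1mp[j, k, t])
                d = yP[j, k, t] - pi
                t_obs += d * d
                yr = 1.0 if np.random.random() < pi else 0.0
                d = yr - pi
                t_rep += d * d
    return t_obs, t_rep


@njit(cache=True)
def _gof_band(yB, f_i, site_i, sex_i, phi, e0, e1eff, w_buf):
    """Sample the alive trajectory exactly (death-time enumeration) and
    accumulate the squared-loss discrepancy on observed and replicate data."""
    I, T = yB.shape
    t_obs = 0.0
    t_rep = 0.0
    for i in range(I):
        fi = f_i[i]
        if fi >= T - 1:
            continue
        pB = 1.0 / (1.0 + math.exp(-(e0 + e1eff * sex_i[i])))
        j = site_i[i]
        last = fi
        for t in range(fi + 1, T):
            if yB[i, t] == 1:
                last = t
        # death year d in {last+1, ..., T-1} or T = survived the study
        n_opt = T - last
        wsum = 0.0
        run = 1.0
        for t in range(fi + 1, last + 1):
            run *= phi[j, t] * (pB if yB[i, t] == 1 else 1.0 - pB)
        for m in range(n_opt):
            d = last + 1 + m
            w = run
            if d <= T - 1:
                w *= 1.0 - phi[j, d]
            w_buf[m] = w
            wsum += w
            if d <= T - 1:
                run *= phi[j, d] * (1.0 - pB)
        u = np.random.random() * wsum
        acc = 0.0
        death = T
        for m in range(n_opt):
            acc += w_buf[m]
            if u <= acc:
                death = last + 1 + m
                break
        for t in range(fi + 1, T):
            z = 1.0 if t < death else 0.0
            pr = z * pB
            d0_ = yB[i, t] - pr
            t_obs += d0_ * d0_
            yr = 1.0 if np.random.random() < pr else 0.0
            d1_ = yr - pr
            t_rep += d1_ * d1_
    return t_obs, t_rep


# ---- the chain -------------------------------------------------------------

@njit(cache=True)
def run_chain(
    yP, sampled, have_point,
    yB, f_i, site_i, sex_i, have_band,
    dnbr, nboxc, tfire, snag, live, transect, obs_assign,
    n_transects, n_observers,
    prior_kind, prior_mean, prior_sd, unif_lo, unif_hi,
    active, selectable, theta_init, v_init,
    N_init, S_init, G_init,
    trans_ptr, trans_sites, obs_ptr, obs_cj, obs_ck, obs_ct,
    n_iter, burn_in, thin, seed,
    update_params, do_select, update_latent,
):
    np.random.seed(seed)
    J, K, T = yP.shape
    ntheta = theta_init.shape[0]
    id2 = NFIXED + n_transects

    theta = theta_init.copy()
    v = v_init.astype(np.float64)
    N = N_init.copy()
    S = S_init.copy()
    G = G_init.copy()

    tfire0 = np.empty(J)
    for j in range(J):
        tfire0[j] = tfire[j, 0]

    lam = np.empty(J)
    phi = np.empty((J, T))
    gam = np.empty((J, T))
    log1mp = np.empty((J, K, T))
    lam_p = np.empty(J)
    phi_p = np.empty((J, T))
    gam_p = np.empty((J, T))
    log1mp_p = np.empty((J, K, T))
    ptab = np.empty((2, n_observers))
    phi[:, 0] = 0.5
    gam[:, 0] = 1.0
    phi_p[:, 0] = 0.5
    gam_p[:, 0] = 1.0

    _calc_lam(lam, theta, v, dnbr, nboxc, tfire0, transect)
    _calc_phi(phi, theta, v, nboxc, tfire, snag, live)
    _calc_gam(gam, theta, v, nboxc, tfire, snag, live)
    _calc_log1mp(log1mp, theta, v, nboxc, obs_assign, id2, ptab)

    step = np.full(ntheta, 0.3)
    acc = np.zeros(ntheta)
    trials = np.zeros(ntheta)

    n_save = (n_iter - burn_in) // thin
    theta_out = np.empty((n_save, ntheta))
    v_out = np.empty((n_save, NV), dtype=np.int8)
    phi_out = np.empty((n_save, J, T), dtype=np.float32)
    N_out = np.empty((n_save, J, T), dtype=np.int16)
    G_out = np.empty((n_save, J, T), dtype=np.int16)
    gof_out = np.zeros((n_save, 4))
    w_buf = np.empty(T + 1)

    ll_cjs_c = _ll_cjs(yB, f_i, site_i, sex_i, phi,
                       theta[IE0], theta[IE1] * v[VE1]) if have_band else 0.0

    isave = 0
    for it in range(n_iter):
        # ---------------- latent abundance sweep ----------------
        if have_point and update_latent:
            for j in range(J):
                # N1
                n0 = N[j, 0]
                prop = n0 + 1 if np.random.random() < 0.5 else n0 - 1
                if prop >= 0 and (T == 1 or S[j, 1] <= prop):
                    d = _d_pois(n0, prop, lam[j])
                    d += _d_obs_incr(yP, sampled, log1mp, j, 0, n0, prop)
                    if T > 1:
                        d += _d_bin_n(S[j, 1], n0, prop, phi[j, 1])
                    if d > 0.0 or np.random.random() < math.exp(d):
                        N[j, 0] = prop
                for t in range(1, T):
                    nprev = N[j, t - 1]
                    # survivors +-1
                    s0 = S[j, t]
                    sp = s0 + 1 if np.random.random() < 0.5 else s0 - 1
                    if 0 <= sp <= nprev:
                        nn = sp + G[j, t]
                        if t == T - 1 or S[j, t + 1] <= nn:
                            d = _d_bin_s(s0, sp, nprev, phi[j, t])
                            d += _d_obs_incr(yP, sampled, log1mp, j, t,
                                             N[j, t], nn)
                            if t < T - 1:
                                d += _d_bin_n(S[j, t + 1], N[j, t], nn,
                                              phi[j, t + 1])
                            if d > 0.0 or np.random.random() < math.exp(d):
                                S[j, t] = sp
                                N[j, t] = nn
                    # recruits +-1
                    g0 = G[j, t]
                    gp = g0 + 1 if np.random.random() < 0.5 else g0 - 1
                    if gp >= 0:
                        nn = S[j, t] + gp
                        if t == T - 1 or S[j, t + 1] <= nn:
                            d = _d_pois(g0, gp, gam[j, t])
                            d += _d_obs_incr(yP, sampled, log1mp, j, t,
                                             N[j, t], nn)
                            if t < T - 1:
                                d += _d_bin_n(S[j, t + 1], N[j, t], nn,
                                              phi[j, t + 1])
                            if d > 0.0 or np.random.random() < math.exp(d):
                                G[j, t] = gp
                                N[j, t] = nn
                    # exchange S <-> G at fixed N
                    delta = 1 if np.random.random() < 0.5 else -1
                    sp = S[j, t] + delta
                    gp = G[j, t] - delta
                    if 0 <= sp <= nprev and gp >= 0:
                        d = _d_bin_s(S[j, t], sp, nprev, phi[j, t])
                        d += _d_pois(G[j, t], gp, gam[j, t])
                        if d > 0.0 or np.random.random() < math.exp(d):
                            S[j, t] = sp
                            G[j, t] = gp

        # ---------------- refresh component caches ----------------
        if have_point:
            ll_lam_c = _ll_lam_red(lam, N)
            ll_surv_c = _ll_surv_red(phi, N, S)
            ll_rec_c = _ll_rec_red(gam, G)
            ll_obs_c = _ll_obsP(yP, sampled, log1mp, N)
        else:
            ll_lam_c = 0.0
            ll_surv_c = 0.0
            ll_rec_c = 0.0
            ll_obs_c = 0.0

        # ---------------- continuous parameter updates ----------------
        if update_params:
            # a block + transect effects (initial-abundance component)
            if have_point:
                for idx in range(IA0, IA3 + 1):
                    if not active[idx]:
                        continue
                    old = theta[idx]
                    new = old + step[idx] * np.random.normal()
                    dp = (_lprior(idx, new, theta, prior_kind, prior_mean,
                                  prior_sd, unif_lo, unif_hi)
                          - _lprior(idx, old, theta, prior_kind, prior_mean,
                                    prior_sd, unif_lo, unif_hi))
                    trials[idx] += 1.0
                    if dp > NEG_INF / 2:
                        theta[idx] = new
                        _calc_lam(lam_p, theta, v, dnbr, nboxc, tfire0, transect)
                        ll_new = _ll_lam_red(lam_p, N)
                        d = ll_new - ll_lam_c + dp
                        if d > 0.0 or np.random.random() < math.exp(d):
                            lam[:] = lam_p
                            ll_lam_c = ll_new
                            acc[idx] += 1.0
                        else:
                            theta[idx] = old
                # transect effects: only that transect's sites change
                for r in range(n_transects):
                    idx = NFIXED + r
                    if not active[idx]:
                        continue
                    old = theta[idx]
                    new = old + step[idx] * np.random.normal()
                    dp = (_lprior(idx, new, theta, prior_kind, prior_mean,
                                  prior_sd, unif_lo, unif_hi)
                          - _lprior(idx, old, theta, prior_kind, prior_mean,
                                    prior_sd, unif_lo, unif_hi))
                    trials[idx] += 1.0
                    dlp = v[VA4] * (new - old)
                    dll = 0.0
                    if dlp != 0.0:
                        fac = math.exp(dlp)
                        for q in range(trans_ptr[r], trans_ptr[r + 1]):
                            j = trans_sites[q]
                            dll += N[j, 0] * dlp - lam[j] * (fac - 1.0)
                    d = dll + dp
                    if d > 0.0 or np.random.random() < math.exp(d):
                        theta[idx] = new
                        if dlp != 0.0:
                            for q in range(trans_ptr[r], trans_ptr[r + 1]):
                                lam[trans_sites[q]] *= fac
                            ll_lam_c += dll
                        acc[idx] += 1.0
                # sigma_a: uniform prior, hierarchical normal over a4
                if active[ISA]:
                    old = theta[ISA]
                    new = old + step[ISA] * np.random.normal()
                    trials[ISA] += 1.0
                    if unif_lo[ISA] <= new <= unif_hi[ISA] and new > 1e-6:
                        d = 0.0
                        for r in range(n_transects):
                            x = theta[NFIXED + r]
                            d += (-math.log(new) - 0.5 * (x / new) ** 2
                                  + math.log(old) + 0.5 * (x / old) ** 2)
                        if d > 0.0 or np.random.random() < math.exp(d):
                            theta[ISA] = new
                            acc[ISA] += 1.0

            # b block (survival: binomial component + CJS component)
            for idx in range(IB0, IB4 + 1):
                if not active[idx]:
                    continue
                old = theta[idx]
                new = old + step[idx] * np.random.normal()
                dp = (_lprior(idx, new, theta, prior_kind, prior_mean,
                              prior_sd, unif_lo, unif_hi)
                      - _lprior(idx, old, theta, prior_kind, prior_mean,
                                prior_sd, unif_lo, unif_hi))
                trials[idx] += 1.0
                theta[idx] = new
                _calc_phi(phi_p, theta, v, nboxc, tfire, snag, live)
                d = dp
                ll_surv_new = ll_surv_c
                ll_cjs_new = ll_cjs_c
                if have_point:
                    ll_surv_new = _ll_surv_red(phi_p, N, S)
                    d += ll_surv_new - ll_surv_c
                if have_band:
                    ll_cjs_new = _ll_cjs(yB, f_i, site_i, sex_i, phi_p,
                                         theta[IE0], theta[IE1] * v[VE1])
                    d += ll_cjs_new - ll_cjs_c
                if d > 0.0 or np.random.random() < math.exp(d):
                    phi[:] = phi_p
                    ll_surv_c = ll_surv_new
                    ll_cjs_c = ll_cjs_new
                    acc[idx] += 1.0
                else:
                    theta[idx] = old

            # c block (recruitment component)
            if have_point:
                for idx in range(IC0, IC4 + 1):
                    if not active[idx]:
                        continue
                    old = theta[idx]
                    new = old + step[idx] * np.random.normal()
                    dp = (_lprior(idx, new, theta, prior_kind, prior_mean,
                                  prior_sd, unif_lo, unif_hi)
                          - _lprior(idx, old, theta, prior_kind, prior_mean,
                                    prior_sd, unif_lo, unif_hi))
                    trials[idx] += 1.0
                    theta[idx] = new
                    _calc_gam(gam_p, theta, v, nboxc, tfire, snag, live)
                    ll_new = _ll_rec_red(gam_p, G)
                    d = ll_new - ll_rec_c + dp
                    if d > 0.0 or np.random.random() < math.exp(d):
                        gam[:] = gam_p
                        ll_rec_c = ll_new
                        acc[idx] += 1.0
                    else:
                        theta[idx] = old

                # d block (observation component)
                for idx in (ID0, ID1):
                    if not active[idx]:
                        continue
                    old = theta[idx]
                    new = old + step[idx] * np.random.normal()
                    dp = (_lprior(idx, new, theta, prior_kind, prior_mean,
                                  prior_sd, unif_lo, unif_hi)
                          - _lprior(idx, old, theta, prior_kind, prior_mean,
                                    prior_sd, unif_lo, unif_hi))
                    trials[idx] += 1.0
                    theta[idx] = new
                    _calc_log1mp(log1mp_p, theta, v, nboxc, obs_assign, id2, ptab)
                    ll_new = _ll_obsP(yP, sampled, log1mp_p, N)
                    d = ll_new - ll_obs_c + dp
                    if d > 0.0 or np.random.random() < math.exp(d):
                        log1mp[:] = log1mp_p
                        ll_obs_c = ll_new
                        acc[idx] += 1.0
                    else:
                        theta[idx] = old
                # observer effects: only that observer's surveyed cells change
                d1eff = theta[ID1] * v[VD1]
                for o in range(n_observers):
                    idx = id2 + o
                    if not active[idx]:
                        continue
                    old = theta[idx]
                    new = old + step[idx] * np.random.normal()
                    dp = (_lprior(idx, new, theta, prior_kind, prior_mean,
                                  prior_sd, unif_lo, unif_hi)
                          - _lprior(idx, old, theta, prior_kind, prior_mean,
                                    prior_sd, unif_lo, unif_hi))
                    trials[idx] += 1.0
                    dll = 0.0
                    if v[VD2] != 0.0:
                        l_new0 = -_softplus(theta[ID0] + v[VD2] * new)
                        l_new1 = -_softplus(theta[ID0] + d1eff + v[VD2] * new)
                        bad = False
                        for q in range(obs_ptr[o], obs_ptr[o + 1]):
                            j = obs_cj[q]
                            k = obs_ck[q]
                            t = obs_ct[q]
                            ln = l_new1 if nboxc[j] > 0.5 else l_new0
                            n = N[j, t]
                            if yP[j, k, t] == 1:
                                if n == 0:
                                    bad = True
                                    break
                                dll += (math.log(-math.expm1(n * ln))
                                        - math.log(-math.expm1(n * log1mp[j, k, t])))
                            else:
                                dll += n * (ln - log1mp[j, k, t])
                        if bad:
                            continue
                    d = dll + dp
                    if d > 0.0 or np.random.random() < math.exp(d):
                        theta[idx] = new
                        if v[VD2] != 0.0:
                            for q in range(obs_ptr[o], obs_ptr[o + 1]):
                                j = obs_cj[q]
                                k = obs_ck[q]
                                t = obs_ct[q]
                                log1mp[j, k, t] = (l_new1 if nboxc[j] > 0.5
                                                   else l_new0)
                            ll_obs_c += dll
                        acc[idx] += 1.0

                # sigma_d
                if active[ISD]:
                    old = theta[ISD]
                    new = old + step[ISD] * np.random.normal()
                    trials[ISD] += 1.0
                    if unif_lo[ISD] <= new <= unif_hi[ISD] and new > 1e-6:
                        d = 0.0
                        for o in range(n_observers):
                            x = theta[id2 + o]
                            d += (-math.log(new) - 0.5 * (x / new) ** 2
                                  + math.log(old) + 0.5 * (x / old) ** 2)
                        if d > 0.0 or np.random.random() < math.exp(d):
                            theta[ISD] = new
                            acc[ISD] += 1.0

            # e block (band-detection component)
            if have_band:
                for idx in (IE0, IE1):
                    if not active[idx]:
                        continue
                    old = theta[idx]
                    new = old + step[idx] * np.random.normal()
                    dp = (_lprior(idx, new, theta, prior_kind, prior_mean,
                                  prior_sd, unif_lo, unif_hi)
                          - _lprior(idx, old, theta, prior_kind, prior_mean,
                                    prior_sd, unif_lo, unif_hi))
                    trials[idx] += 1.0
                    if dp > NEG_INF / 2:
                        theta[idx] = new
                        ll_new = _ll_cjs(yB, f_i, site_i, sex_i, phi,
                                         theta[IE0], theta[IE1] * v[VE1])
                        d = ll_new - ll_cjs_c + dp
                        if d > 0.0 or np.random.random() < math.exp(d):
                            ll_cjs_c = ll_new
                            acc[idx] += 1.0
                        else:
                            theta[idx] = old

        # ---------------- indicator Gibbs sweep ----------------
        if do_select:
            for slot in range(NV):
                if not selectable[slot]:
                    continue
                vold = v[slot]
                v[slot] = 1.0 - vold
                ll_surv_new = ll_surv_c
                ll_cjs_new = ll_cjs_c
                if slot <= VA4:
                    _calc_lam(lam_p, theta, v, dnbr, nboxc, tfire0, transect)
                    ll_alt = _ll_lam_red(lam_p, N)
                    ll_cur = ll_lam_c
                elif slot <= VB4:
                    _calc_phi(phi_p, theta, v, nboxc, tfire, snag, live)
                    ll_alt = 0.0
                    ll_cur = 0.0
                    if have_point:
                        ll_surv_new = _ll_surv_red(phi_p, N, S)
                        ll_alt += ll_surv_new
                        ll_cur += ll_surv_c
                    if have_band:
                        ll_cjs_new = _ll_cjs(yB, f_i, site_i, sex_i, phi_p,
                                             theta[IE0], theta[IE1] * v[VE1])
                        ll_alt += ll_cjs_new
                        ll_cur += ll_cjs_c
                elif slot <= VC4:
                    _calc_gam(gam_p, theta, v, nboxc, tfire, snag, live)
                    ll_alt = _ll_rec_red(gam_p, G)
                    ll_cur = ll_rec_c
                elif slot <= VD2:
                    _calc_log1mp(log1mp_p, theta, v, nboxc, obs_assign, id2, ptab)
                    ll_alt = _ll_obsP(yP, sampled, log1mp_p, N)
                    ll_cur = ll_obs_c
                else:  # VE1
                    ll_alt = _ll_cjs(yB, f_i, site_i, sex_i, phi,
                                     theta[IE0], theta[IE1] * v[VE1])
                    ll_cur = ll_cjs_c
                # Bernoulli(0.5) prior cancels; full conditional on the flip
                p_flip = 1.0 / (1.0 + math.exp(ll_cur - ll_alt))
                if np.random.random() < p_flip:
                    # adopt flipped state
                    if slot <= VA4:
                        lam[:] = lam_p
                        ll_lam_c = ll_alt
                    elif slot <= VB4:
                        phi[:] = phi_p
                        ll_surv_c = ll_surv_new
                        ll_cjs_c = ll_cjs_new
                    elif slot <= VC4:
                        gam[:] = gam_p
                        ll_rec_c = ll_alt
                    elif slot <= VD2:
                        log1mp[:] = log1mp_p
                        ll_obs_c = ll_alt
                    else:
                        ll_cjs_c = ll_alt
                else:
                    v[slot] = vold

            # refresh excluded coefficients from their priors (Kuo-Mallick)
            for slot in range(NV):
                if not selectable[slot] or v[slot] != 0.0:
                    continue
                if slot == VA4:
                    for r in range(n_transects):
                        theta[NFIXED + r] = np.random.normal() * theta[ISA]
                elif slot == VD2:
                    for o in range(n_observers):
                        theta[id2 + o] = np.random.normal() * theta[ISD]
                else:
                    if slot == VA1:
                        idx = IA1
                    elif slot == VA2:
                        idx = IA2
                    elif slot == VA3:
                        idx = IA3
                    elif slot == VB1:
                        idx = IB1
                    elif slot == VB2:
                        idx = IB2
                    elif slot == VB3:
                        idx = IB3
                    elif slot == VB4:
                        idx = IB4
                    elif slot == VC1:
                        idx = IC1
                    elif slot == VC2:
                        idx = IC2
                    elif slot == VC3:
                        idx = IC3
                    elif slot == VC4:
                        idx = IC4
                    elif slot == VD1:
                        idx = ID1
                    else:
                        idx = IE1
                    theta[idx] = (prior_mean[idx]
                                  + np.random.normal() * prior_sd[idx])

        # ---------------- adaptation (burn-in only) ----------------
        if it < burn_in and (it + 1) % 100 == 0:
            for idx in range(ntheta):
                if trials[idx] > 0.0:
                    rate = acc[idx] / trials[idx]
                    fac = math.exp(rate - 0.35)
                    s = step[idx] * fac
                    step[idx] = min(max(s, 1e-3), 10.0)
                    acc[idx] = 0.0
                    trials[idx] = 0.0

        # ---------------- save ----------------
        if it >= burn_in and (it - burn_in) % thin == 0 and isave < n_save:
            for q in range(ntheta):
                theta_out[isave, q] = theta[q]
            for q in range(NV):
                v_out[isave, q] = np.int8(v[q])
            for j in range(J):
                for t in range(T):
                    phi_out[isave, j, t] = phi[j, t]
                    N_out[isave, j, t] = N[j, t]
                    G_out[isave, j, t] = G[j, t]
            if have_point:
                to, tr = _gof_point(yP, sampled, log1mp, N)
                gof_out[isave, 0] = to
                gof_out[isave, 1] = tr
            if have_band:
                to, tr = _gof_band(yB, f_i, site_i, sex_i, phi,
                                   theta[IE0], theta[IE1] * v[VE1], w_buf)
                gof_out[isave, 2] = to
                gof_out[isave, 3] = tr
            isave += 1

    return theta_out, v_out, phi_out, N_out, G_out, gof_out, step
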
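"""Numba kernels: packed forward likelihood and the reference MCMC chain.

The forward recursion is evaluated on packed integer/float arrays.  A shared
"never seen again" table chi[t, state, age] (probability of no detection
after year t given the latent state and age at t) is computed once per
likelihood evaluation by backward recursion; each individual then only needs
the forward pass over its detected span, which keeps a full-dataset
evaluation fast enough to sit inside a Metropolis-within-Gibbs sweep.

State coding matches model_core: 0 pre-breeder, 1 non-breeder, 2 failed
breeder, 3 successful breeder, 4 dead.  Year-effect rows: reproduction in
year t reads row t; survival into year t reads row t (type-1 pairing) or
row t-1 (type-2 pairing).
"""

import math

import numpy as np
from numba import njit

PB, NB, FB, SB, DEAD = 0, 1, 2, 3, 4

# model tuple layout (see inference.build_packed_model):
#  0 T, 1 A, 2 corr_type, 3 has_pb, 4 K,
#  5 col_phij, 6 col_phiad, 7 col_psi, 8 col_pi, 9 col_om, 10 family,
#  11 ac_phi, 12 ac_psi, 13 ac_pi, 14 ac_om, 15 ac_p,
#  16 i_mu_phi, 17 i_mu_psi, 18 i_mu_pi, 19 i_mu_om, 20 i_mu_p, 21 i_lsig_om,
#  22 f_phi_idx, 23 f_psi_idx, 24 f_pi_idx, 25 f_om_idx, 26 f_p_idx,
#  27 g_phi_idx, 28 g_psi_idx, 29 g_pi_idx, 30 g_p_idx, 31 fixed_p
# data tuple layout: (entry, entry_state, last_det, det, obs_state, cnt, weight)
# weight carries the multiplicity of collapsed identical capture histories.


@njit(cache=True)
def _invlogit(x):
    return 1.0 / (1.0 + math.exp(-x))


@njit(cache=True)
def _count_logprob(c, eta, family, sig_om):
    """Log-probability of count c; eta is the link-scale location."""
    if c < 1.0:
        return -np.inf
    if family == 0:
        return 0.0 if c == 1.0 else -np.inf
    if family == 1:  # Bernoulli on >1 offspring, logit link
        q = _invlogit(eta)
        return math.log(q) if c >= 2.0 else math.log(1.0 - q)
    if family == 2:  # normal truncated at 0, identity link
        z = (c - eta) / sig_om
        logdens = -0.5 * z * z - math.log(sig_om) - 0.9189385332046727
        lognorm = math.log(0.5 * math.erfc(-eta / (sig_om * 1.4142135623730951)))
        return logdens - lognorm
    lam = math.exp(eta)  # Poisson truncated at 0, log link
    return c * eta - lam - math.lgamma(c + 1.0) - math.log(1.0 - math.exp(-lam))


@njit(cache=True)
def loglik_total(theta, alpha, alpha_p, model, data):
    (T, A, corr_type, has_pb, K,
     col_phij, col_phiad, col_psi, col_pi, col_om, family,
     ac_phi, ac_psi, ac_pi, ac_om, ac_p,
     i_mu_phi, i_mu_psi, i_mu_pi, i_mu_om, i_mu_p, i_lsig_om,
     f_phi_idx, f_psi_idx, f_pi_idx, f_om_idx, f_p_idx,
     g_phi_idx, g_psi_idx, g_pi_idx, g_p_idx, fixed_p) = model
    entry, entry_state, last_det, det, obs_state, cnt, weight = data

    psi_active = col_psi >= 0
    pi_active = col_pi >= 0
    om_active = col_om >= 0
    p_free = i_mu_p >= 0
    sig_om = math.exp(theta[i_lsig_om]) if i_lsig_om >= 0 else 1.0

    # --- linear-predictor tables by age and (previous) state ---------------
    lp_phi = np.empty((A + 1, 4))
    lp_psi = np.empty((A + 1, 4))
    lp_pi = np.empty((A + 1, 4))
    lp_om = np.empty(A + 1)
    lp_p = np.empty((A + 1, 4))
    colphi = np.empty(A + 1, dtype=np.int64)
    for a in range(A + 1):
        c = ac_phi[a]
        base = theta[i_mu_phi] + (theta[f_phi_idx[c]] if f_phi_idx[c] >= 0 else 0.0)
        juvenile = a == 1
        colphi[a] = col_phij if juvenile else col_phiad
        for s in range(4):
            g = theta[g_phi_idx[s]] if (g_phi_idx[s] >= 0 and not juvenile) else 0.0
            lp_phi[a, s] = base + g
        if psi_active:
            c = ac_psi[a]
            base = theta[i_mu_psi] + (theta[f_psi_idx[c]] if f_psi_idx[c] >= 0 else 0.0)
            for s in range(4):
                g = theta[g_psi_idx[s]] if (g_psi_idx[s] >= 0 and not juvenile) else 0.0
                lp_psi[a, s] = base + g
        if pi_active:
            c = ac_pi[a]
            base = theta[i_mu_pi] + (theta[f_pi_idx[c]] if f_pi_idx[c] >= 0 else 0.0)
            for s in range(4):
                g = theta[g_pi_idx[s]] if (g_pi_idx[s] >= 0 and not juvenile) else 0.0
                lp_pi[a, s] = base + g
        if om_active:
            c = ac_om[a]
            lp_om[a] = theta[i_mu_om] + (theta[f_om_idx[c]] if f_om_idx[c] >= 0 else 0.0)
        if p_free:
            c = ac_p[a]
            base = theta[i_mu_p] + (theta[f_p_idx[c]] if f_p_idx[c] >= 0 else 0.0)
            for s in range(4):
                g = theta[g_p_idx[s]] if g_p_idx[s] >= 0 else 0.0
                lp_p[a, s] = base + g

    # --- chi[t, s, a]: P(never detected after t | state s, age a at t) ----
    chi = np.ones((T, 5, A + 1))
    for t in range(T - 2, -1, -1):
        tn = t + 1
        srow = tn if corr_type == 1 else tn - 1
        for a in range(A + 1):
            an = a + 1 if a + 1 < A else A
            for s in range(4):
                phi = _invlogit(lp_phi[an, s] + alpha[srow, colphi[an]])
                psi = _invlogit(lp_psi[an, s] + alpha[tn, col_psi]) if psi_active else 1.0
                pi = _invlogit(lp_pi[an, s] + alpha[tn, col_pi]) if pi_active else 1.0
                dnb = PB if (has_pb == 1 and s == PB) else NB
                acc = 1.0 - phi
                if p_free:
                    p_nb = _invlogit(lp_p[an, dnb] + alpha_p[tn])
                    p_fb = _invlogit(lp_p[an, FB] + alpha_p[tn])
                    p_sb = _invlogit(lp_p[an, SB] + alpha_p[tn])
                else:
                    p_nb = fixed_p
                    p_fb = fixed_p
                    p_sb = fixed_p
                acc += phi * (1.0 - psi) * (1.0 - p_nb) * chi[tn, dnb, an]
                acc += phi * psi * (1.0 - pi) * (1.0 - p_fb) * chi[tn, FB, an]
                acc += phi * psi * pi * (1.0 - p_sb) * chi[tn, SB, an]
                chi[t, s, a] = acc

    # --- forward pass over each detected span ------------------------------
    total = 0.0
    n = entry.shape[0]
    f = np.zeros(5)
    g = np.zeros(5)
    for i in range(n):
        e = entry[i]
        L = last_det[i]
        for s in range(5):
            f[s] = 0.0
        f[entry_state[i]] = 1.0
        ll = 0.0
        for t in range(e + 1, L + 1):
            a = t - e if t - e < A else A
            srow = t if corr_type == 1 else t - 1
            for s in range(5):
                g[s] = 0.0
            for s in range(4):
                fs = f[s]
                if fs == 0.0:
                    continue
                phi = _invlogit(lp_phi[a, s] + alpha[srow, colphi[a]])
                psi = _invlogit(lp_psi[a, s] + alpha[t, col_psi]) if psi_active else 1.0
                pi = _invlogit(lp_pi[a, s] + alpha[t, col_pi]) if pi_active else 1.0
                g[DEAD] += fs * (1.0 - phi)
                dnb = PB if (has_pb == 1 and s == PB) else NB
                g[dnb] += fs * phi * (1.0 - psi)
                g[FB] += fs * phi * psi * (1.0 - pi)
                g[SB] += fs * phi * psi * pi
            g[DEAD] += f[DEAD]
            if det[i, t] == 1:
                o = obs_state[i, t]
                po = _invlogit(lp_p[a, o] + alpha_p[t]) if p_free else fixed_p
                w = g[o] * po
                if o == SB and cnt[i, t] >= 0.0:
                    eta = lp_om[a] + alpha[t, col_om] if om_active else 0.0
                    w *= math.exp(_count_logprob(cnt[i, t], eta,
                                                 family if om_active else 0, sig_om))
                for s in range(5):
                    g[s] = 0.0
                g[o] = w
                norm = w
            else:
                for s in range(4):
                    po = _invlogit(lp_p[a, s] + alpha_p[t]) if p_free else fixed_p
                    g[s] *= 1.0 - po
                norm = g[0] + g[1] + g[2] + g[3] + g[4]
            if norm <= 0.0:
                return -np.inf
            ll += math.log(norm)
            for s in range(5):
                f[s] = g[s] / norm
        aL = L - e if L - e < A else A
        tail = 0.0
        for s in range(5):
            tail += f[s] * chi[L, s, aL]
        if tail <= 0.0:
            return -np.inf
        total += weight[i] * (ll + math.log(tail))
    return total


# ---------------------------------------------------------------------------
# Priors on the expanded-Cholesky covariance block
# ---------------------------------------------------------------------------

@njit(cache=True)
def _row_mvn_logpdf(x, Lam):
    """log N(x; 0, Lam Lam^T) via forward substitution (Lam lower triangular,
    diagonal entries may be negative under the expanded parameterisation)."""
    K = x.shape[0]
    logdet = 0.0
    for k in range(K):
        d = abs(Lam[k, k])
        if d < 1e-12:
            return -np.inf
        logdet += math.log(d)
    quad = 0.0
    y = np.empty(K)
    for k in range(K):
        acc = x[k]
        for j in range(k):
            acc -= Lam[k, j] * y[j]
        y[k] = acc / Lam[k, k]
        quad += y[k] * y[k]
    return -0.5 * quad - logdet - 0.9189385332046727 * K


@njit(cache=True)
def _alpha_prior_total(alpha, Lam):
    total = 0.0
    for t in range(alpha.shape[0]):
        total += _row_mvn_logpdf(alpha[t], Lam)
    return total


@njit(cache=True)
def _norm_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.9189385332046727


# ---------------------------------------------------------------------------
# Adaptive Metropolis-within-Gibbs chain
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_chain(seed, n_iter, n_burn, thin,
              theta0, alpha0, alpha_p0, Lam0, log_sp0,
              prior_mean, prior_sd, loading_sd, scale_sd_p,
              trans_idx, trans_mask, trans_p,
              model, data):
    """One MCMC chain.  Blocks: each fixed-effect scalar; each year's
    (alpha row, alpha_p) jointly; each free loading of the covariance
    factor; log sigma_p; plus likelihood-invariant translation moves
    (intercept vs year-effect mean, described by trans_*) and joint
    rescaling moves (year-effect column vs covariance loadings) that break
    the funnel geometry of the centred parameterisation.  Random-walk
    proposals with Robbins-Monro scale adaptation during burn-in only."""
    np.random.seed(seed)
    T = model[0]
    K = model[4]
    n_theta = theta0.shape[0]
    est_p = model[20] >= 0  # i_mu_p: detection year effects only when p is free

    theta = theta0.copy()
    alpha = alpha0.copy()
    alpha_p = alpha_p0.copy()
    Lam = Lam0.copy()
    log_sp = log_sp0

    cur_ll = loglik_total(theta, alpha, alpha_p, model, data)
    cur_apri = _alpha_prior_total(alpha, Lam)

    s_theta = np.full(n_theta, 0.1)
    s_year = np.full(T, 0.3)
    s_lam = np.full((K, K), 0.1)
    s_sp = 0.3
    s_scale = np.full(K, 0.3)
    s_scale_p = 0.3
    M = trans_idx.shape[0]
    s_trans = np.full(M, 0.2)
    s_pcn = np.full(K, 0.5)
    s_pcn_p = 0.5

    n_keep = (n_iter - n_burn) // thin
    out_theta = np.empty((n_keep, n_theta))
    out_Lam = np.empty((n_keep, K, K))
    out_sp = np.empty(n_keep)
    out_alpha = np.empty((n_keep, T, K))
    out_alpha_p = np.empty((n_keep, T))
    out_ll = np.empty(n_keep)

    acc_theta = np.zeros(n_theta)
    acc_year = np.zeros(T)

    kept = 0
    for it in range(n_iter):
        gamma = min(0.05, 5.0 / (it + 10.0)) if it < n_burn else 0.0

        # --- fixed effects -------------------------------------------------
        for j in range(n_theta):
            old = theta[j]
            theta[j] = old + s_theta[j] * np.random.normal()
            new_ll = loglik_total(theta, alpha, alpha_p, model, data)
            dpri = (_norm_logpdf(theta[j] - prior_mean[j], prior_sd[j])
                    - _norm_logpdf(old - prior_mean[j], prior_sd[j]))
            if math.log(np.random.random()) < new_ll - cur_ll + dpri:
                cur_ll = new_ll
                if it >= n_burn:
                    acc_theta[j] += 1.0
                if gamma > 0.0:
                    s_theta[j] *= math.exp(gamma * (1.0 - 0.44))
            else:
                theta[j] = old
                if gamma > 0.0:
                    s_theta[j] *= math.exp(-gamma * 0.44)

        # --- year effects (alpha row + detection effect jointly) -----------
        sp = math.exp(log_sp)
        for t in range(T):
            old_row = alpha[t].copy()
            old_ap = alpha_p[t]
            old_rpri = _row_mvn_logpdf(alpha[t], Lam)
            for k in range(K):
                alpha[t, k] = old_row[k] + s_year[t] * np.random.normal()
            if est_p:
                alpha_p[t] = old_ap + s_year[t] * np.random.normal()
            new_ll = loglik_total(theta, alpha, alpha_p, model, data)
            new_rpri = _row_mvn_logpdf(alpha[t], Lam)
            dpri = new_rpri - old_rpri
            if est_p:
                dpri += (_norm_logpdf(alpha_p[t], sp) - _norm_logpdf(old_ap, sp))
            if math.log(np.random.random()) < new_ll - cur_ll + dpri:
                cur_ll = new_ll
                cur_apri += new_rpri - old_rpri
                if it >= n_burn:
                    acc_year[t] += 1.0
                if gamma > 0.0:
                    s_year[t] *= math.exp(gamma * (1.0 - 0.28))
            else:
                for k in range(K):
                    alpha[t, k] = old_row[k]
                alpha_p[t] = old_ap
                if gamma > 0.0:
                    s_year[t] *= math.exp(-gamma * 0.28)

        # --- covariance factor loadings ------------------------------------
        # data-free given alpha, so several cheap sweeps per iteration
        for _sweep in range(8):
            for r in range(K):
                for c in range(r + 1):
                    old = Lam[r, c]
                    Lam[r, c] = old + s_lam[r, c] * np.random.normal()
                    new_apri = _alpha_prior_total(alpha, Lam)
                    dpri = (_norm_logpdf(Lam[r, c], loading_sd)
                            - _norm_logpdf(old, loading_sd))
                    if math.log(np.random.random()) < new_apri - cur_apri + dpri:
                        cur_apri = new_apri
                        if gamma > 0.0:
                            s_lam[r, c] *= math.exp(gamma * (1.0 - 0.44))
                    else:
                        Lam[r, c] = old
                        if gamma > 0.0:
                            s_lam[r, c] *= math.exp(-gamma * 0.44)

        # --- translations: intercept up, matching year-effect mean down -----
        # The linear predictors are invariant, so the data likelihood drops
        # out and only the priors decide.
        for m in range(M):
            j = trans_idx[m]
            delta = s_trans[m] * np.random.normal()
            new_tj = theta[j] + delta
            dpri = (_norm_logpdf(new_tj - prior_mean[j], prior_sd[j])
                    - _norm_logpdf(theta[j] - prior_mean[j], prior_sd[j]))
            if trans_p[m] == 1:
                sp = math.exp(log_sp)
                for t in range(T):
                    dpri += (_norm_logpdf(alpha_p[t] - delta, sp)
                             - _norm_logpdf(alpha_p[t], sp))
                if math.log(np.random.random()) < dpri:
                    theta[j] = new_tj
                    for t in range(T):
                        alpha_p[t] -= delta
                    if gamma > 0.0:
                        s_trans[m] *= math.exp(gamma * (1.0 - 0.44))
                elif gamma > 0.0:
                    s_trans[m] *= math.exp(-gamma * 0.44)
            else:
                for k in range(K):
                    if trans_mask[m, k] > 0.0:
                        for t in range(T):
                            alpha[t, k] -= delta
                new_apri = _alpha_prior_total(alpha, Lam)
                if math.log(np.random.random()) < dpri + new_apri - cur_apri:
                    theta[j] = new_tj
                    cur_apri = new_apri
                    if gamma > 0.0:
                        s_trans[m] *= math.exp(gamma * (1.0 - 0.44))
                else:
                    for k in range(K):
                        if trans_mask[m, k] > 0.0:
                            for t in range(T):
                                alpha[t, k] += delta
                    if gamma > 0.0:
                        s_trans[m] *= math.exp(-gamma * 0.44)

        # --- pCN refresh of whole year-effect columns -----------------------
        # Proposes column k from (a Crank-Nicolson blend with) its
        # conditional prior given the other columns; detailed balance with
        # respect to the MVN prior leaves the data-likelihood ratio as the
        # whole acceptance probability.  Weakly informed columns regenerate
        # wholesale, which the row-wise random walk cannot do.
        Sigma = Lam @ Lam.T
        for k in range(K):
            vk = Sigma[k, k]
            if K > 1:
                Am = np.empty((K - 1, K - 1))
                cm = np.empty(K - 1)
                ii = 0
                for a in range(K):
                    if a == k:
                        continue
                    cm[ii] = Sigma[a, k]
                    jj = 0
                    for b in range(K):
                        if b == k:
                            continue
                        Am[ii, jj] = Sigma[a, b]
                        jj += 1
                    ii += 1
                ok = True
                for a in range(K - 1):
                    if Am[a, a] <= 1e-12:
                        ok = False
                if not ok:
                    continue
                bvec = np.linalg.solve(Am, cm)
                vk = Sigma[k, k] - cm @ bvec
            if vk <= 1e-12:
                continue
            s = s_pcn[k]
            rho = math.sqrt(max(0.0, 1.0 - s * s))
            sd = math.sqrt(vk)
            old_col = alpha[:, k].copy()
            for t in range(T):
                m = 0.0
                if K > 1:
                    ii = 0
                    for a in range(K):
                        if a == k:
                            continue
                        m += bvec[ii] * alpha[t, a]
                        ii += 1
                alpha[t, k] = m + rho * (old_col[t] - m) + s * sd * np.random.normal()
            new_ll = loglik_total(theta, alpha, alpha_p, model, data)
            if math.log(np.random.random()) < new_ll - cur_ll:
                cur_ll = new_ll
                cur_apri = _alpha_prior_total(alpha, Lam)
                if gamma > 0.0:
                    s_pcn[k] = min(1.0, s_pcn[k] * math.exp(gamma * (1.0 - 0.30)))
            else:
                for t in range(T):
                    alpha[t, k] = old_col[t]
                if gamma > 0.0:
                    s_pcn[k] = min(1.0, s_pcn[k] * math.exp(-gamma * 0.30))

        if est_p:
            sp = math.exp(log_sp)
            s = s_pcn_p
            rho = math.sqrt(max(0.0, 1.0 - s * s))
            old_ap = alpha_p.copy()
            for t in range(T):
                alpha_p[t] = rho * old_ap[t] + s * sp * np.random.normal()
            new_ll = loglik_total(theta, alpha, alpha_p, model, data)
            if math.log(np.random.random()) < new_ll - cur_ll:
                cur_ll = new_ll
                if gamma > 0.0:
                    s_pcn_p = min(1.0, s_pcn_p * math.exp(gamma * (1.0 - 0.30)))
            else:
                for t in range(T):
                    alpha_p[t] = old_ap[t]
                if gamma > 0.0:
                    s_pcn_p = min(1.0, s_pcn_p * math.exp(-gamma * 0.30))

        # --- joint rescaling of (alpha column k, loading row k) -------------
        # Scale moves exchange mass between "small sigma, small effects" and
        # "large sigma, large effects" configurations, which single-site
        # updates traverse very slowly (the classic funnel).  The MVN prior
        # term and the alpha-Jacobian cancel exactly, leaving the data
        # likelihood, the loading priors and the loading Jacobian.
        for k in range(K):
            eps = s_scale[k] * np.random.normal()
            c = math.exp(eps)
            for t in range(T):
                alpha[t, k] *= c
            dpri = 0.0
            for j in range(k + 1):
                dpri -= _norm_logpdf(Lam[k, j], loading_sd)
                Lam[k, j] *= c
                dpri += _norm_logpdf(Lam[k, j], loading_sd)
            new_ll = loglik_total(theta, alpha, alpha_p, model, data)
            if math.log(np.random.random()) < (new_ll - cur_ll + dpri
                                               + (k + 1) * eps):
                cur_ll = new_ll
                cur_apri = _alpha_prior_total(alpha, Lam)
                if gamma > 0.0:
                    s_scale[k] *= math.exp(gamma * (1.0 - 0.44))
            else:
                inv = math.exp(-eps)
                for t in range(T):
                    alpha[t, k] *= inv
                for j in range(k + 1):
                    Lam[k, j] *= inv
                if gamma > 0.0:
                    s_scale[k] *= math.exp(-gamma * 0.44)

        # --- joint rescaling of (alpha_p, sigma_p) ---------------------------
        if est_p:
            eps = s_scale_p * np.random.normal()
            c = math.exp(eps)
            for t in range(T):
                alpha_p[t] *= c
            sp_old = math.exp(log_sp)
            sp_new = sp_old * c
            new_ll = loglik_total(theta, alpha, alpha_p, model, data)
            d = (new_ll - cur_ll + eps
                 - 0.5 * (sp_new / scale_sd_p) ** 2 + 0.5 * (sp_old / scale_sd_p) ** 2)
            if math.log(np.random.random()) < d:
                cur_ll = new_ll
                log_sp += eps
                if gamma > 0.0:
                    s_scale_p *= math.exp(gamma * (1.0 - 0.44))
            else:
                inv = math.exp(-eps)
                for t in range(T):
                    alpha_p[t] *= inv
                if gamma > 0.0:
                    s_scale_p *= math.exp(-gamma * 0.44)

        # --- detection-effect scale ----------------------------------------
        if est_p:
            old = log_sp
            log_sp = old + s_sp * np.random.normal()
            sp_new = math.exp(log_sp)
            sp_old = math.exp(old)
            d = 0.0
            for t in range(T):
                d += _norm_logpdf(alpha_p[t], sp_new) - _norm_logpdf(alpha_p[t], sp_old)
            # half-normal prior on sigma_p plus the log-transform Jacobian
            d += (-0.5 * (sp_new / scale_sd_p) ** 2 + 0.5 * (sp_old / scale_sd_p) ** 2
                  + (log_sp - old))
            if math.log(np.random.random()) < d:
                if gamma > 0.0:
                    s_sp *= math.exp(gamma * (1.0 - 0.44))
            else:
                log_sp = old
                if gamma > 0.0:
                    s_sp *= math.exp(-gamma * 0.44)

        # --- store ----------------------------------------------------------
        if it >= n_burn and (it - n_burn) % thin == 0 and kept < n_keep:
            out_theta[kept] = theta
            out_Lam[kept] = Lam
            out_sp[kept] = math.exp(log_sp)
            out_alpha[kept] = alpha
            out_alpha_p[kept] = alpha_p
            out_ll[kept] = cur_ll
            kept += 1

    n_post = max(1, n_iter - n_burn)
    return (out_theta, out_Lam, out_sp, out_alpha, out_alpha_p, out_ll,
            acc_theta / n_post, acc_year / n_post)
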
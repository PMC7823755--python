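"""Numba kernel for the single-step BayesC Gibbs sampler.

One compiled function runs the whole chain.  Update order per iteration:

1. fixed effects (including breed-fraction and J regressions) as one
   multivariate-normal block draw with a flat prior, via a precomputed
   Cholesky factor of F'F;
2. each marker's (inclusion indicator, effect) from the collapsed BayesC
   full conditional: the indicator is drawn with the effect integrated out,
   then the effect from its normal conditional when included;
3. residual polygenic effects u, single-site, using the sparse pedigree
   precision A⁻¹/(w σ_g²);
4. imputation residuals ε for non-genotyped animals, single-site, using the
   non-genotyped block of A⁻¹ divided by (1 − w) σ_g² (that block is the
   inverse of A_nn − A_ng A_gg⁻¹ A_gn, so no dense Schur factorization is
   formed);
5. variances from scaled-inverse-χ² full conditionals when not running in
   fixed-variance mode.

A running residual vector over the phenotyped records is maintained
throughout, so every conditional costs a dot product against the records.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _chol_solve_lower(L, b):  # pragma: no cover
    """Solve (L L') x = b for lower-triangular L."""
    n = L.shape[0]
    y = np.empty(n)
    for i in range(n):
        s = b[i]
        for j in range(i):
            s -= L[i, j] * y[j]
        y[i] = s / L[i, i]
    x = np.empty(n)
    for i in range(n - 1, -1, -1):
        s = y[i]
        for j in range(i + 1, n):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def _solve_upper(L, z):  # pragma: no cover
    """Solve L' x = z for lower-triangular L (i.e. back substitution)."""
    n = L.shape[0]
    x = np.empty(n)
    for i in range(n - 1, -1, -1):
        s = z[i]
        for j in range(i + 1, n):
            s -= L[j, i] * x[j]
        x[i] = s / L[i, i]
    return x


@njit(cache=True)
def run_chain(  # noqa: C901 - one long kernel by design
    y,                # (nr,) phenotypes (training records)
    F,                # (nr, nf) fixed-effect design (X | D | J)
    FtF_chol,         # (nf, nf) lower Cholesky of F'F
    MpT,              # (p, nr) marker covariates of record animals, row-major
    MfT,              # (p, N) marker covariates of every animal, row-major
    ck,               # (p,) diagonal m_k'm_k
    rec_of_animal,    # (N,) record index per animal, -1 if unphenotyped
    ainv_indptr, ainv_indices, ainv_data,   # CSR of A^-1 (N x N)
    q_indptr, q_indices, q_data,            # CSR of [A^-1]_nn (nn x nn)
    rec_of_eps,       # (nn,) record index per non-genotyped animal, -1
    animal_of_eps,    # (nn,) animal index per non-genotyped animal
    pi, w,
    sigma_g2_init, sigma_a2_init, sigma_e2_init,
    nu_g, S2_g, nu_a, S2_a, nu_e, S2_e,
    sample_sigma_e, sample_sigma_a, sample_sigma_g,
    n_inner_sweeps,
    n_iter, burn_in, thin, seed,
    # outputs
    beta_draws, alpha_draws, delta_draws, u_draws, eps_draws,
    sige_draws, sigg_draws, siga_draws,
    gen_sum, gen_sumsq,   # (N,) streaming moments of the genetic part
):  # pragma: no cover - exercised via the Python wrapper
    np.random.seed(seed)
    nr = y.shape[0]
    nf = F.shape[1]
    p = MpT.shape[0]
    N = rec_of_animal.shape[0]
    nn = rec_of_eps.shape[0]

    beta = np.zeros(nf)
    alpha = np.zeros(p)
    delta = np.zeros(p, dtype=np.uint8)
    u = np.zeros(N)
    eps = np.zeros(nn)
    sigma_e2 = sigma_e2_init
    sigma_a2 = sigma_a2_init
    sigma_g2 = sigma_g2_init

    e = y.copy()
    marker_part = np.zeros(N)  # M_full @ alpha, updated incrementally
    log_odds_prior = 0.0
    if 0.0 < pi < 1.0:
        log_odds_prior = np.log((1.0 - pi) / pi)

    keep = 0
    for it in range(n_iter):
        # --- 1. fixed effects: joint block draw, flat prior ---------------
        if nf > 0:
            # residual with fixed effects put back
            r = e.copy()
            for j in range(nf):
                bj = beta[j]
                if bj != 0.0:
                    for i in range(nr):
                        r[i] += F[i, j] * bj
            Ftr = np.empty(nf)
            for j in range(nf):
                s = 0.0
                for i in range(nr):
                    s += F[i, j] * r[i]
                Ftr[j] = s
            mean = _chol_solve_lower(FtF_chol, Ftr)
            z = np.empty(nf)
            for j in range(nf):
                z[j] = np.random.standard_normal()
            pert = _solve_upper(FtF_chol, z)
            se = np.sqrt(sigma_e2)
            for j in range(nf):
                beta[j] = mean[j] + se * pert[j]
            # rebuild the residual from r
            for i in range(nr):
                s = r[i]
                for j in range(nf):
                    s -= F[i, j] * beta[j]
                e[i] = s

        # --- 2. markers: collapsed BayesC update --------------------------
        if p > 0 and sigma_a2 > 0.0:
            for k in range(p):
                c = ck[k]
                a_old = alpha[k]
                if c > 0.0:
                    rhs = c * a_old
                    for i in range(nr):
                        rhs += MpT[k, i] * e[i]
                    if pi <= 0.0:
                        incl = True
                    elif pi >= 1.0:
                        incl = False
                    else:
                        v0 = c * sigma_e2
                        v1 = c * c * sigma_a2 + c * sigma_e2
                        lo = (
                            log_odds_prior
                            + 0.5 * np.log(v0 / v1)
                            + 0.5 * rhs * rhs * (1.0 / v0 - 1.0 / v1)
                        )
                        if lo > 35.0:
                            incl = True
                        elif lo < -35.0:
                            incl = False
                        else:
                            incl = np.random.random() < 1.0 / (1.0 + np.exp(-lo))
                    if incl:
                        lhs = c + sigma_e2 / sigma_a2
                        a_new = rhs / lhs + np.random.standard_normal() * np.sqrt(
                            sigma_e2 / lhs
                        )
                        delta[k] = 1
                    else:
                        a_new = 0.0
                        delta[k] = 0
                else:
                    # marker constant over training records: prior draw
                    if pi <= 0.0 or (pi < 1.0 and np.random.random() < 1.0 - pi):
                        delta[k] = 1
                        a_new = np.random.standard_normal() * np.sqrt(sigma_a2)
                    else:
                        delta[k] = 0
                        a_new = 0.0
                if a_new != a_old:
                    diff = a_old - a_new
                    for i in range(nr):
                        e[i] += MpT[k, i] * diff
                    for i in range(N):
                        marker_part[i] -= MfT[k, i] * diff
                    alpha[k] = a_new

        # --- 3. residual polygenic effects u ------------------------------
        # single-site updates are cheap next to the marker sweep, so they
        # are repeated within the iteration to cut autocorrelation
        vu = w * sigma_g2
        if vu > 0.0:
          for _sweep in range(n_inner_sweeps):
            for i in range(N):
                diag = 0.0
                offsum = 0.0
                for idx in range(ainv_indptr[i], ainv_indptr[i + 1]):
                    j = ainv_indices[idx]
                    if j == i:
                        diag = ainv_data[idx]
                    else:
                        offsum += ainv_data[idx] * u[j]
                prec = diag / vu
                mean_num = -offsum / vu
                r_i = rec_of_animal[i]
                if r_i >= 0:
                    prec += 1.0 / sigma_e2
                    mean_num += (e[r_i] + u[i]) / sigma_e2
                mu_post = mean_num / prec
                u_new = mu_post + np.random.standard_normal() / np.sqrt(prec)
                if r_i >= 0:
                    e[r_i] += u[i] - u_new
                u[i] = u_new

        # --- 4. imputation residuals eps ----------------------------------
        ve = (1.0 - w) * sigma_g2
        if nn > 0 and ve > 0.0:
          for _sweep in range(n_inner_sweeps):
            for i in range(nn):
                diag = 0.0
                offsum = 0.0
                for idx in range(q_indptr[i], q_indptr[i + 1]):
                    j = q_indices[idx]
                    if j == i:
                        diag = q_data[idx]
                    else:
                        offsum += q_data[idx] * eps[j]
                prec = diag / ve
                mean_num = -offsum / ve
                r_i = rec_of_eps[i]
                if r_i >= 0:
                    prec += 1.0 / sigma_e2
                    mean_num += (e[r_i] + eps[i]) / sigma_e2
                mu_post = mean_num / prec
                eps_new = mu_post + np.random.standard_normal() / np.sqrt(prec)
                if r_i >= 0:
                    e[r_i] += eps[i] - eps_new
                eps[i] = eps_new

        # --- 5. variances --------------------------------------------------
        if sample_sigma_a and p > 0:
            ssq = nu_a * S2_a
            m_in = 0
            for k in range(p):
                if delta[k] == 1:
                    ssq += alpha[k] * alpha[k]
                    m_in += 1
            sigma_a2 = ssq / np.random.chisquare(nu_a + m_in)
        if sample_sigma_g:
            ssq = nu_g * S2_g
            df = nu_g
            if w > 0.0:
                uAu = 0.0
                for i in range(N):
                    s = 0.0
                    for idx in range(ainv_indptr[i], ainv_indptr[i + 1]):
                        s += ainv_data[idx] * u[ainv_indices[idx]]
                    uAu += u[i] * s
                ssq += uAu / w
                df += N
            if nn > 0 and w < 1.0:
                eQe = 0.0
                for i in range(nn):
                    s = 0.0
                    for idx in range(q_indptr[i], q_indptr[i + 1]):
                        s += q_data[idx] * eps[q_indices[idx]]
                    eQe += eps[i] * s
                ssq += eQe / (1.0 - w)
                df += nn
            sigma_g2 = ssq / np.random.chisquare(df)
        if sample_sigma_e:
            ssq = nu_e * S2_e
            for i in range(nr):
                ssq += e[i] * e[i]
            sigma_e2 = ssq / np.random.chisquare(nu_e + nr)
        if not np.isfinite(sigma_e2) or sigma_e2 <= 0.0:
            return it  # divergence: caller raises with seed and iteration

        # --- accumulate genetic part over every post-burn-in iteration ----
        if it >= burn_in:
            for i in range(N):
                gi = marker_part[i] + u[i]
                gen_sum[i] += gi
                gen_sumsq[i] += gi * gi
            for i in range(nn):
                a_i = animal_of_eps[i]
                gi = eps[i]
                # add the eps contribution and correct the moments
                prev = marker_part[a_i] + u[a_i]
                gen_sum[a_i] += gi
                gen_sumsq[a_i] += gi * gi + 2.0 * gi * prev

        # --- store ---------------------------------------------------------
        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(nf):
                beta_draws[keep, j] = beta[j]
            for k in range(p):
                alpha_draws[keep, k] = alpha[k]
                delta_draws[keep, k] = delta[k]
            for i in range(N):
                u_draws[keep, i] = u[i]
            for i in range(nn):
                eps_draws[keep, i] = eps[i]
            sige_draws[keep] = sigma_e2
            sigg_draws[keep] = sigma_g2
            siga_draws[keep] = sigma_a2
            keep += 1
    return -1
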
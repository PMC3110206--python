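"""Numba kernels for the kernel-weighted recursive elastic net.

Everything operates on Gram-space sufficient statistics of the weighted,
standardized problem for one (target, focal sample) pair:

    G = X*' W X*        (q x q)
    c = X*' W y*        (q,)
    yWy = y*' W y*
    n_eff = sum(w)

The objective minimised is

    f(beta) = 1/2 sum_k w_k (y_k - x_k' beta)^2
              + lam1 * sum_j gamma_j |beta_j|
              + lam2/2 * sum_j beta_j^2

so the no-signal boundary is exactly lam_max = max_j |c_j| / gamma_j
(KKT: beta = 0 is optimal iff |c_j| <= lam1 * gamma_j for all j).

Cyclic coordinate descent visits coordinates in fixed input order and
stops when the largest coefficient change in a sweep drops below ``tol``
— determinism is part of the contract.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NONCONVERGED = -1


@njit(cache=True)
def cd_gram(G, c, lam1, lam2, gamma, beta, tol, max_sweeps):
    """In-place cyclic coordinate descent on Gram statistics.

    Returns the number of sweeps used, or NONCONVERGED.
    """
    q = c.size
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(q):
            gb = 0.0
            for l in range(q):
                gb += G[j, l] * beta[l]
            rho = c[j] - gb + G[j, j] * beta[j]
            t = lam1 * gamma[j]
            denom = G[j, j] + lam2
            if denom <= 0.0:
                new = 0.0
            elif rho > t:
                new = (rho - t) / denom
            elif rho < -t:
                new = (rho + t) / denom
            else:
                new = 0.0
            d = abs(new - beta[j])
            if d > max_delta:
                max_delta = d
            beta[j] = new
        if max_delta < tol:
            return sweep + 1
    return NONCONVERGED


@njit(cache=True)
def df_trace_gram(G, active, lam2):
    """trace[(G_AA + lam2 I)^-1 G_AA] — ridge-type hat-matrix trace."""
    a = active.size
    Gaa = np.empty((a, a))
    for i in range(a):
        for j in range(a):
            Gaa[i, j] = G[active[i], active[j]]
    M = Gaa.copy()
    for i in range(a):
        M[i, i] += lam2
    sol = np.linalg.solve(M, Gaa)
    tr = 0.0
    for i in range(a):
        tr += sol[i, i]
    return tr


@njit(cache=True)
def _aicc(rss, df, n_eff):
    if df >= n_eff - 1.0:
        return np.inf
    r = rss if rss > 1e-300 else 1e-300
    return n_eff * np.log(r / n_eff) + 2.0 * df * n_eff / (n_eff - df - 1.0)


@njit(cache=True)
def grid_search_gram(G, c, yWy, n_eff, lam2_grid, n_lam1, lam1_min_ratio,
                     gamma, tol, max_sweeps):
    """One pass over the (lam1, lam2) grid for fixed importance weights.

    The lam1 path is log-spaced from lam_max (empty model) down to
    lam1_min_ratio * lam_max, descending, warm-started within each lam2.
    Ties in AICc break toward smaller df, then larger lam1, then earlier
    grid position.  Returns (beta, df, aicc, lam1, lam2, status) with
    status 1 if any inner solve hit the sweep budget.
    """
    q = c.size
    best_beta = np.zeros(q)
    best_df = 0.0
    best_aicc = np.inf
    best_lam1 = 0.0
    best_lam2 = 0.0
    status = 0

    lam_max = 0.0
    for j in range(q):
        v = abs(c[j]) / gamma[j]
        if v > lam_max:
            lam_max = v
    if lam_max <= 0.0:
        # no predictor carries weighted signal: empty model
        best_aicc = _aicc(yWy, 0.0, n_eff)
        return best_beta, best_df, best_aicc, best_lam1, best_lam2, status

    log_hi = np.log(lam_max)
    log_lo = np.log(lam_max * lam1_min_ratio)
    active = np.empty(q, dtype=np.int64)

    for i2 in range(lam2_grid.size):
        lam2 = lam2_grid[i2]
        beta = np.zeros(q)
        for i1 in range(n_lam1):
            if n_lam1 == 1:
                lam1 = lam_max
            else:
                lam1 = np.exp(log_hi + (log_lo - log_hi) * i1 / (n_lam1 - 1))
            ns = cd_gram(G, c, lam1, lam2, gamma, beta, tol, max_sweeps)
            if ns == NONCONVERGED:
                status = 1
            a = 0
            for j in range(q):
                if beta[j] != 0.0:
                    active[a] = j
                    a += 1
            bGb = 0.0
            bc = 0.0
            for j in range(q):
                if beta[j] != 0.0:
                    bc += beta[j] * c[j]
                    row = 0.0
                    for l in range(q):
                        row += G[j, l] * beta[l]
                    bGb += beta[j] * row
            rss = yWy - 2.0 * bc + bGb
            if rss < 0.0:
                rss = 0.0
            df = 0.0 if a == 0 else df_trace_gram(G, active[:a], lam2)
            aicc = _aicc(rss, df, n_eff)
            better = False
            if aicc < best_aicc:
                better = True
            elif aicc == best_aicc:
                if df < best_df:
                    better = True
                elif df == best_df and lam1 > best_lam1:
                    better = True
            if better:
                best_aicc = aicc
                best_df = df
                best_lam1 = lam1
                best_lam2 = lam2
                for j in range(q):
                    best_beta[j] = beta[j]
    return best_beta, best_df, best_aicc, best_lam1, best_lam2, status


@njit(cache=True)
def fit_recursive_gram(G, c, yWy, n_eff, lam2_grid, n_lam1, lam1_min_ratio,
                       delta, max_iter, tol, max_sweeps):
    """Adaptive (recursive) elastic net with AICc-scored grid search.

    Iteration 1 runs with gamma = 1.  Each subsequent iteration rebuilds
    gamma_j = 1/(|beta_j| + delta) from the previous grid winner and
    re-searches the grid; the loop exits as soon as the grid winner fails
    to improve the incumbent AICc.  Returns the incumbent.
    """
    q = c.size
    gamma = np.ones(q)
    inc_beta = np.zeros(q)
    inc_gamma = np.ones(q)
    inc_df = 0.0
    inc_aicc = np.inf
    inc_lam1 = 0.0
    inc_lam2 = 0.0
    status = 0
    iters = 0
    for it in range(max_iter):
        beta, df, aicc, lam1, lam2, st = grid_search_gram(
            G, c, yWy, n_eff, lam2_grid, n_lam1, lam1_min_ratio,
            gamma, tol, max_sweeps)
        if st != 0:
            status = st
        iters = it + 1
        if it > 0 and aicc >= inc_aicc:
            break
        inc_beta = beta
        inc_gamma = gamma.copy()
        inc_df = df
        inc_aicc = aicc
        inc_lam1 = lam1
        inc_lam2 = lam2
        for j in range(q):
            gamma[j] = 1.0 / (abs(beta[j]) + delta)
    return (inc_beta, inc_gamma, inc_df, inc_aicc, inc_lam1, inc_lam2,
            iters, status)
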
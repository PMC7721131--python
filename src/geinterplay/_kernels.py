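"""Numba-compiled inner loops for the penalized solvers.

All kernels work on precomputed Gram matrices so their cost is independent of the
sample size; the callers own standardization, grids and convergence bookkeeping.
"""

import numba
import numpy as np


@numba.njit(cache=False)
def soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@numba.njit(cache=False)
def enet_cd(G, Xy, n, alpha, lam, beta, tol, max_iter):
    """Cyclic coordinate descent for the 1/(2n) elastic net on a Gram matrix.

    Minimizes (1/2n)||y - Xb||^2 + lam*(alpha*||b||_1 + (1-alpha)/2*||b||_2^2)
    given G = X'X and Xy = X'y. ``beta`` is updated in place (warm start).
    Returns the number of sweeps used.
    """
    p = beta.shape[0]
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    Gb = G @ beta
    for it in range(max_iter):
        delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj / n + l2 <= 0.0:  # constant column, nothing to fit
                continue
            rho = (Xy[j] - Gb[j] + gjj * beta[j]) / n
            new = soft_threshold(rho, l1) / (gjj / n + l2)
            diff = new - beta[j]
            if diff != 0.0:
                for k in range(p):
                    Gb[k] += G[k, j] * diff
                beta[j] = new
                if abs(diff) > delta:
                    delta = abs(diff)
        if delta < tol:
            return it + 1
    return max_iter


@numba.njit(cache=False)
def enet_path_cd(G, Xy, n, alpha, lams, tol, max_iter):
    """Warm-started coordinate-descent path over a decreasing lambda grid."""
    p = Xy.shape[0]
    betas = np.zeros((lams.shape[0], p))
    beta = np.zeros(p)
    for i in range(lams.shape[0]):
        enet_cd(G, Xy, n, alpha, lams[i], beta, tol, max_iter)
        betas[i] = beta
    return betas


@numba.njit(cache=False)
def lassosum_cd(R, r, s, lam, beta, tol, max_iter):
    """Coordinate descent for the summary-statistic penalized regression.

    Minimizes (1-s) b'Rb - 2 b'r + s b'b + 2*lam*||b||_1 over one LD block,
    with R the SNP correlation matrix of the reference panel. ``beta`` is
    updated in place. Returns sweeps used.
    """
    m = beta.shape[0]
    Rb = R @ beta
    for it in range(max_iter):
        delta = 0.0
        for j in range(m):
            rjj = R[j, j]
            z = r[j] - (1.0 - s) * (Rb[j] - rjj * beta[j])
            new = soft_threshold(z, lam) / ((1.0 - s) * rjj + s)
            diff = new - beta[j]
            if diff != 0.0:
                for k in range(m):
                    Rb[k] += R[k, j] * diff
                beta[j] = new
                if abs(diff) > delta:
                    delta = abs(diff)
        if delta < tol:
            return it + 1
    return max_iter


@numba.njit(cache=False)
def _group_objective(Gf, fty, lam, coef, feat, group_start, group_len, weights):
    F = Gf.shape[0]
    f = np.zeros(F)
    for d in range(coef.shape[0]):
        f[feat[d]] += coef[d]
    quad = 0.5 * f @ (Gf @ f) - fty @ f
    pen = 0.0
    for g in range(group_start.shape[0]):
        s = group_start[g]
        nrm = 0.0
        for k in range(group_len[g]):
            nrm += coef[s + k] * coef[s + k]
        pen += weights[g] * np.sqrt(nrm)
    return quad + lam * pen


@numba.njit(cache=False)
def group_fista(Gf, fty, lam, feat, group_start, group_len, weights, L,
                coef, tol, max_iter):
    """Monotone FISTA for the overlapped group lasso in latent coordinates.

    The latent coefficient vector ``coef`` (updated in place, warm start) maps to
    feature space through ``feat`` (each latent coordinate adds into one feature
    column); ``Gf`` = F'F/n and ``fty`` = F'y/n are feature-space moments. Groups
    are contiguous latent index ranges. A candidate step is only accepted when it
    does not increase the objective, so the objective is non-increasing.
    Returns iterations used.
    """
    D = coef.shape[0]
    F = Gf.shape[0]
    x = coef.copy()
    z = coef.copy()
    t = 1.0
    obj = _group_objective(Gf, fty, lam, x, feat, group_start, group_len, weights)
    for it in range(max_iter):
        # gradient of the smooth part at z
        f = np.zeros(F)
        for d in range(D):
            f[feat[d]] += z[d]
        gf = Gf @ f - fty
        cand = np.empty(D)
        for d in range(D):
            cand[d] = z[d] - gf[feat[d]] / L
        # group soft-thresholding
        for g in range(group_start.shape[0]):
            s = group_start[g]
            nrm = 0.0
            for k in range(group_len[g]):
                nrm += cand[s + k] * cand[s + k]
            nrm = np.sqrt(nrm)
            thr = lam * weights[g] / L
            if nrm <= thr:
                for k in range(group_len[g]):
                    cand[s + k] = 0.0
            else:
                scale = 1.0 - thr / nrm
                for k in range(group_len[g]):
                    cand[s + k] *= scale
        obj_cand = _group_objective(Gf, fty, lam, cand, feat, group_start,
                                    group_len, weights)
        if obj_cand > obj:
            # restart momentum from the best iterate; objective never increases
            z = x.copy()
            t = 1.0
            continue
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        for d in range(D):
            z[d] = cand[d] + ((t - 1.0) / t_new) * (cand[d] - x[d])
        # the latent decomposition is not unique, so convergence is judged on
        # the (strictly decreasing) objective alone
        rel = (obj - obj_cand) / (abs(obj) + 1e-12)
        x = cand.copy()
        obj = obj_cand
        t = t_new
        if it > 0 and rel < tol:
            for d in range(D):
                coef[d] = x[d]
            return it + 1
    for d in range(D):
        coef[d] = x[d]
    return max_iter
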
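"""Numba kernels for the profiled ML deviance of the longitudinal mixed model.

Model per subject i (m_i observations):

    y_i = X_i beta + Z_i b_i + e_i,   b_i ~ N(0, sigma2 * Psi),  e_i ~ N(0, sigma2 * I)

with Psi the residual-scaled random-effects covariance (q x q, q <= 2). For a
given Psi, beta and sigma2 have closed GLS/ML forms, so the deviance is profiled
down to the q(q+1)/2 free elements of Psi. The marginal precision is expanded
with the Woodbury identity, so each evaluation only touches per-subject q x q
cross-products precomputed once per design:

    A_i = Z_i' Z_i,  B_i = Z_i' X_i,  c_i = Z_i' y_i,
    Sxx = sum X_i' X_i,  Sxy = sum X_i' y_i,  Syy = sum y_i' y_i.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_2PI = float(np.log(2.0 * np.pi))
_BIG = 1.0e300


@njit(cache=True, fastmath=False)
def deviance_q2(psi, A, B, c, sxx, sxy, syy, n_obs):
    """Profiled -2 lnL for a 2-dim random effect (intercept + slope).

    Returns (deviance, beta, sigma2, sxx_adj); deviance is huge when Psi is
    numerically inadmissible or the profiled residual variance is <= 0.
    """
    s = B.shape[0]
    p = B.shape[2]
    t_xx = np.zeros((p, p))
    t_xy = np.zeros(p)
    t_yy = 0.0
    logdet = 0.0
    p00 = psi[0, 0]
    p01 = psi[0, 1]
    p11 = psi[1, 1]
    u = np.empty((2, p))
    for i in range(s):
        a00 = A[i, 0, 0]
        a01 = A[i, 0, 1]
        a11 = A[i, 1, 1]
        # M = I + A_i Psi (A_i and Psi symmetric)
        m00 = 1.0 + a00 * p00 + a01 * p01
        m01 = a00 * p01 + a01 * p11
        m10 = a01 * p00 + a11 * p01
        m11 = 1.0 + a01 * p01 + a11 * p11
        det = m00 * m11 - m01 * m10
        if det <= 1.0e-300:
            return _BIG, np.zeros(p), 1.0, np.eye(p)
        logdet += np.log(det)
        i00 = m11 / det
        i01 = -m01 / det
        i10 = -m10 / det
        i11 = m00 / det
        # W = Psi @ inv(M); symmetric in exact arithmetic
        w00 = p00 * i00 + p01 * i10
        w01 = p00 * i01 + p01 * i11
        w10 = p01 * i00 + p11 * i10
        w11 = p01 * i01 + p11 * i11
        w01 = 0.5 * (w01 + w10)
        # U = W @ B_i
        for a in range(p):
            u[0, a] = w00 * B[i, 0, a] + w01 * B[i, 1, a]
            u[1, a] = w01 * B[i, 0, a] + w11 * B[i, 1, a]
        for a in range(p):
            b0a = B[i, 0, a]
            b1a = B[i, 1, a]
            for b in range(p):
                t_xx[a, b] += b0a * u[0, b] + b1a * u[1, b]
        v0 = w00 * c[i, 0] + w01 * c[i, 1]
        v1 = w01 * c[i, 0] + w11 * c[i, 1]
        for a in range(p):
            t_xy[a] += B[i, 0, a] * v0 + B[i, 1, a] * v1
        t_yy += c[i, 0] * v0 + c[i, 1] * v1
    sxx_adj = sxx - t_xx
    sxx_adj = 0.5 * (sxx_adj + sxx_adj.T)
    sxy_adj = sxy - t_xy
    beta = np.linalg.solve(sxx_adj, sxy_adj)
    rss = syy - t_yy - beta @ sxy_adj
    if rss <= 0.0 or not np.isfinite(rss):
        return _BIG, np.zeros(p), 1.0, np.eye(p)
    sigma2 = rss / n_obs
    dev = n_obs * (_LOG_2PI + np.log(sigma2) + 1.0) + logdet
    return dev, beta, sigma2, sxx_adj


@njit(cache=True, fastmath=False)
def _dev_theta_q2(t, A, B, c, sxx, sxy, syy, n_obs):
    """Deviance as a function of the log-Cholesky parameters (q = 2)."""
    t0 = min(max(t[0], -12.0), 12.0)
    t1 = min(max(t[1], -12.0), 12.0)
    t2 = min(max(t[2], -12.0), 12.0)
    l00 = np.exp(t0)
    l11 = np.exp(t1)
    psi = np.empty((2, 2))
    psi[0, 0] = l00 * l00
    psi[0, 1] = l00 * t2
    psi[1, 0] = l00 * t2
    psi[1, 1] = t2 * t2 + l11 * l11
    return deviance_q2(psi, A, B, c, sxx, sxy, syy, n_obs)[0]


@njit(cache=True, fastmath=False)
def nelder_mead_q2(x0, step, A, B, c, sxx, sxy, syy, n_obs,
                   maxiter, fatol, xatol):
    """Nelder-Mead on the 3 variance parameters, fully jitted.

    Standard reflect/expand/contract/shrink coefficients (1, 2, 0.5, 0.5).
    Returns (best_theta, best_deviance, converged).
    """
    ndim = 3
    npts = ndim + 1
    sim = np.empty((npts, ndim))
    fvals = np.empty(npts)
    for j in range(ndim):
        sim[0, j] = x0[j]
    for i in range(ndim):
        for j in range(ndim):
            sim[i + 1, j] = x0[j]
        sim[i + 1, i] += step
    for i in range(npts):
        fvals[i] = _dev_theta_q2(sim[i], A, B, c, sxx, sxy, syy, n_obs)

    converged = False
    for _ in range(maxiter):
        order = np.argsort(fvals)
        sim = sim[order]
        fvals = fvals[order]
        fspread = fvals[-1] - fvals[0]
        xspread = 0.0
        for i in range(1, npts):
            for j in range(ndim):
                d = abs(sim[i, j] - sim[0, j])
                if d > xspread:
                    xspread = d
        if fspread <= fatol and xspread <= xatol:
            converged = True
            break
        centroid = np.zeros(ndim)
        for i in range(npts - 1):
            for j in range(ndim):
                centroid[j] += sim[i, j]
        centroid /= (npts - 1)
        xr = 2.0 * centroid - sim[-1]
        fr = _dev_theta_q2(xr, A, B, c, sxx, sxy, syy, n_obs)
        if fr < fvals[0]:
            xe = centroid + 2.0 * (centroid - sim[-1])
            fe = _dev_theta_q2(xe, A, B, c, sxx, sxy, syy, n_obs)
            if fe < fr:
                sim[-1] = xe
                fvals[-1] = fe
            else:
                sim[-1] = xr
                fvals[-1] = fr
        elif fr < fvals[-2]:
            sim[-1] = xr
            fvals[-1] = fr
        else:
            if fr < fvals[-1]:
                xc = centroid + 0.5 * (xr - centroid)
            else:
                xc = centroid + 0.5 * (sim[-1] - centroid)
            fc = _dev_theta_q2(xc, A, B, c, sxx, sxy, syy, n_obs)
            if fc < min(fr, fvals[-1]):
                sim[-1] = xc
                fvals[-1] = fc
            else:
                for i in range(1, npts):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    fvals[i] = _dev_theta_q2(sim[i], A, B, c, sxx, sxy, syy,
                                             n_obs)
    order = np.argsort(fvals)
    return sim[order[0]], fvals[order[0]], converged


@njit(cache=True, fastmath=False)
def deviance_q1(psi00, A, B, c, sxx, sxy, syy, n_obs):
    """Profiled -2 lnL for a 1-dim random effect (intercept-only or slope-only)."""
    s = B.shape[0]
    p = B.shape[2]
    t_xx = np.zeros((p, p))
    t_xy = np.zeros(p)
    t_yy = 0.0
    logdet = 0.0
    for i in range(s):
        m = 1.0 + A[i, 0, 0] * psi00
        if m <= 1.0e-300:
            return _BIG, np.zeros(p), 1.0, np.eye(p)
        logdet += np.log(m)
        w = psi00 / m
        for a in range(p):
            ba = B[i, 0, a]
            for b in range(p):
                t_xx[a, b] += ba * w * B[i, 0, b]
            t_xy[a] += ba * w * c[i, 0]
        t_yy += c[i, 0] * w * c[i, 0]
    sxx_adj = sxx - t_xx
    sxx_adj = 0.5 * (sxx_adj + sxx_adj.T)
    sxy_adj = sxy - t_xy
    beta = np.linalg.solve(sxx_adj, sxy_adj)
    rss = syy - t_yy - beta @ sxy_adj
    if rss <= 0.0 or not np.isfinite(rss):
        return _BIG, np.zeros(p), 1.0, np.eye(p)
    sigma2 = rss / n_obs
    dev = n_obs * (_LOG_2PI + np.log(sigma2) + 1.0) + logdet
    return dev, beta, sigma2, sxx_adj
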
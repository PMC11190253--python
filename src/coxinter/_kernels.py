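"""Numba kernels for Cox partial-likelihood estimation.

All kernels operate on arrays pre-sorted by observed time in *descending*
order, so each risk set is a prefix and the risk-set sums

    S0 = sum eta_i,   S1 = sum eta_i x_i,   S2 = sum eta_i x_i x_i',
    S3[a] = sum eta_i x_ia x_i x_i'   (third moments, Firth only)

accumulate incrementally.  Ties are handled by the Breslow convention: every
subject whose time equals the current event time (including subjects censored
at that time) is entered into the sums before any event at that time is
processed.  The generator produces no tied event times, only shared
administrative-censoring times, so Breslow and Efron coincide here.

The Firth-modified score uses the analytic derivative of the information
matrix.  Per event with risk-set mean ``m = S1/S0`` and covariance
``V = S2/S0 - m m'`` one has ``dm[b]/dbeta[a] = V[a,b]`` and

    dV[b,c]/dbeta[a] = S3[a,b,c]/S0 - m[a] S2[b,c]/S0
                       - V[a,b] m[c] - m[b] V[a,c].
"""

import numpy as np
from numba import njit

__all__ = ["cox_stats", "newton_fit"]


@njit(cache=True)
def cox_stats(time, d, X, beta, firth):
    """Objective value, (modified) score and information at ``beta``.

    Returns ``(value, score, info, ok)`` where ``value`` is the partial
    log-likelihood (penalized by ``0.5*log det I`` when ``firth``), ``score``
    the gradient (Firth-modified when ``firth``), ``info`` the *unpenalized*
    observed information, and ``ok`` is False when the information is not
    positive definite (Firth penalty undefined / singular system).
    """
    n, p = X.shape
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    s3 = np.zeros((p, p, p))
    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    dI = np.zeros((p, p, p))
    m = np.zeros(p)
    V = np.zeros((p, p))

    i = 0
    while i < n:
        j = i
        ti = time[i]
        while j < n and time[j] == ti:
            j += 1
        # enter the whole tie group into the risk set
        for k in range(i, j):
            lp = 0.0
            for a in range(p):
                lp += X[k, a] * beta[a]
            eta = np.exp(lp)
            s0 += eta
            for a in range(p):
                xa = eta * X[k, a]
                s1[a] += xa
                for b in range(p):
                    xab = xa * X[k, b]
                    s2[a, b] += xab
                    if firth:
                        for c in range(p):
                            s3[a, b, c] += xab * X[k, c]
        # process events at this time
        for k in range(i, j):
            if d[k] == 1:
                lp = 0.0
                for a in range(p):
                    lp += X[k, a] * beta[a]
                ll += lp - np.log(s0)
                for a in range(p):
                    m[a] = s1[a] / s0
                for a in range(p):
                    U[a] += X[k, a] - m[a]
                    for b in range(p):
                        V[a, b] = s2[a, b] / s0 - m[a] * m[b]
                        I[a, b] += V[a, b]
                if firth:
                    for a in range(p):
                        for b in range(p):
                            for c in range(p):
                                dI[a, b, c] += (
                                    s3[a, b, c] / s0
                                    - m[a] * s2[b, c] / s0
                                    - V[a, b] * m[c]
                                    - m[b] * V[a, c]
                                )
        i = j

    ok = True
    if firth:
        det = np.linalg.det(I)
        if not np.isfinite(det) or det <= 0.0:
            ok = False
        else:
            ll += 0.5 * np.log(det)
            Iinv = np.linalg.inv(I)
            for a in range(p):
                tr = 0.0
                for b in range(p):
                    for c in range(p):
                        tr += Iinv[b, c] * dI[a, c, b]
                U[a] += 0.5 * tr
    return ll, U, I, ok


@njit(cache=True)
def newton_fit(time, d, X, firth, free, beta0, maxiter, maxstep, tol):
    """Newton-Raphson on the (penalized) partial likelihood.

    Coordinates with ``free[j] == False`` are held at their ``beta0`` value
    (profile fits).  The Newton increment is rescaled so its largest
    coordinate moves at most ``maxstep``, which bounds the per-iteration
    travel while preserving the ascent direction; a step that does not
    increase the objective is halved (up to 5 times) before being accepted,
    damping the overshoot that occurs because the unpenalized information
    approximates the penalized Hessian.
    The fit converges iff the maximum absolute (modified) score over free
    coordinates drops below ``tol`` in fewer than ``maxiter`` iterations; a
    singular information matrix flags non-convergence.

    Returns ``(beta, value, score, info, converged, iterations, singular)``.
    """
    p = X.shape[1]
    beta = beta0.copy()
    nf = 0
    for a in range(p):
        if free[a]:
            nf += 1
    idx = np.empty(nf, dtype=np.int64)
    k = 0
    for a in range(p):
        if free[a]:
            idx[k] = a
            k += 1

    ll, U, I, ok = cox_stats(time, d, X, beta, firth)
    if not ok:
        return beta, ll, U, I, False, 0, True
    for it in range(maxiter + 1):
        gmax = 0.0
        for a in range(nf):
            g = abs(U[idx[a]])
            if g > gmax:
                gmax = g
        if gmax < tol:
            return beta, ll, U, I, it < maxiter, it, False
        if it == maxiter:
            return beta, ll, U, I, False, it, False
        # free-coordinate Newton step, clipped per coordinate
        If = np.empty((nf, nf))
        Uf = np.empty(nf)
        for a in range(nf):
            Uf[a] = U[idx[a]]
            for b in range(nf):
                If[a, b] = I[idx[a], idx[b]]
        det = np.linalg.det(If)
        if not np.isfinite(det) or det <= 0.0:
            return beta, ll, U, I, False, it, True
        delta = np.linalg.solve(If, Uf)
        dmax = 0.0
        for a in range(nf):
            if abs(delta[a]) > dmax:
                dmax = abs(delta[a])
        if dmax > maxstep:
            scale = maxstep / dmax
            for a in range(nf):
                delta[a] *= scale
        # accept the first (possibly halved) step that improves the objective
        accepted = False
        for half in range(6):
            cand = beta.copy()
            for a in range(nf):
                cand[idx[a]] += delta[a]
            ll_new, U_new, I_new, ok = cox_stats(time, d, X, cand, firth)
            if ok and (ll_new > ll or half == 5):
                beta, ll, U, I = cand, ll_new, U_new, I_new
                accepted = True
                break
            for a in range(nf):
                delta[a] *= 0.5
        if not accepted:
            return beta, ll, U, I, False, it + 1, True
    return beta, ll, U, I, False, maxiter, False
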
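"""Naive O(n^2) reference implementation of the Cox partial likelihood.

Deliberately independent of the package's sorted-prefix kernels: risk sets
are recomputed from scratch for every event by direct comparison of times.
Used as a brute-force oracle in tests; never imported by the package.
"""

import numpy as np


def naive_loglik(time, event, X, beta):
    """Breslow partial log-likelihood via explicit risk sets."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    beta = np.asarray(beta, float)
    eta = np.exp(X @ beta)
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += X[i] @ beta - np.log(eta[risk].sum())
    return ll


def naive_score_info(time, event, X, beta):
    """Score vector and observed information via explicit risk sets."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    beta = np.asarray(beta, float)
    p = X.shape[1]
    eta = np.exp(X @ beta)
    U = np.zeros(p)
    I = np.zeros((p, p))
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        w = eta[risk] / eta[risk].sum()
        m = w @ X[risk]
        U += X[i] - m
        I += (X[risk] * w[:, None]).T @ X[risk] - np.outer(m, m)
    return U, I


def naive_firth_objective(time, event, X, beta):
    """Penalized log-likelihood l(beta) + 0.5 log det I(beta)."""
    _, I = naive_score_info(time, event, X, beta)
    sign, logdet = np.linalg.slogdet(I)
    if sign <= 0:
        return -np.inf
    return naive_loglik(time, event, X, beta) + 0.5 * logdet


def grid_maximize(objective, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force 1-D maximization on a regular grid."""
    grid = np.arange(lo, hi + step, step)
    vals = np.array([objective(b) for b in grid])
    return grid[int(np.argmax(vals))], vals.max()
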
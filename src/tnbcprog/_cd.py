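"""Coordinate-descent kernel for the penalized weighted least-squares step."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sweep(X, w, r, beta, xv, lam_l1, lam_l2, active_only):
    """One coordinate-descent pass; returns the largest coefficient change."""
    n, p = X.shape
    dmax = 0.0
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        num = xv[j] * bj
        for i in range(n):
            num += w[i] * X[i, j] * r[i]
        if num > lam_l1:
            bn = (num - lam_l1) / (xv[j] + lam_l2)
        elif num < -lam_l1:
            bn = (num + lam_l1) / (xv[j] + lam_l2)
        else:
            bn = 0.0
        d = bn - bj
        if d != 0.0:
            for i in range(n):
                r[i] -= d * X[i, j]
            beta[j] = bn
            ad = abs(d)
            if ad > dmax:
                dmax = ad
    return dmax


@njit(cache=True)
def cd_solve(X, w, z, beta, eta, lam_l1, lam_l2, tol, max_sweeps):
    """One penalized WLS solve by cyclic coordinate descent.

    Minimizes  0.5 * sum_i w_i (z_i - x_i' beta)^2
             + lam_l1 * ||beta||_1 + 0.5 * lam_l2 * ||beta||_2^2
    in place; ``eta`` is updated to X @ beta.  Uses active-set cycling: a
    full pass over all coordinates, then passes over the current nonzero
    set until stable, repeated until a full pass changes nothing.
    """
    n, p = X.shape
    r = np.empty(n)
    for i in range(n):
        r[i] = z[i] - eta[i]
    xv = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        xv[j] = s
    sweeps = 0
    while sweeps < max_sweeps:
        dmax = _sweep(X, w, r, beta, xv, lam_l1, lam_l2, False)
        sweeps += 1
        if dmax < tol:
            break
        while sweeps < max_sweeps:
            dmax = _sweep(X, w, r, beta, xv, lam_l1, lam_l2, True)
            sweeps += 1
            if dmax < tol:
                break
    for i in range(n):
        eta[i] = z[i] - r[i]
    return sweeps
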
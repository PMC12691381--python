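"""Numba-compiled coordinate-descent core for elastic-net logistic paths.

Solves, for a descending sequence of penalties lambda,

    min_{b0, beta}  -(1/n) sum_i [y_i log p_i + (1-y_i) log(1-p_i)]
                    + lambda * [ (1-alpha)/2 ||beta||_2^2 + alpha ||beta||_1 ]

with p_i = sigmoid(b0 + x_i beta) and an unpenalized intercept, via
iteratively reweighted least squares with cyclic coordinate descent on
the weighted working response (the glmnet algorithm).  Features may be
standardized internally; returned coefficients are always on the
original scale.  Fitted probabilities are clipped to [1e-5, 1-1e-5]
inside the IRLS weights for numerical stability.

Everything here is hot-loop code for leave-one-out and permutation
resampling; keep it free of Python objects.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PMIN = 1e-5
_MAX_IRLS = 200
_MAX_CD = 2000


@njit(cache=True)
def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def fit_path(X, y, lambdas, alpha, standardize, tol):
    """Path of original-scale coefficients, shape (n_lambda, p + 1).

    Column 0 is the intercept.  Warm starts run down the (descending)
    lambda sequence.  A single-class response yields the intercept-only
    model at every lambda.  Zero-variance features are kept at zero.
    """
    n, p = X.shape
    L = lambdas.shape[0]
    B = np.zeros((L, p + 1))

    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        pc = min(max(ybar, PMIN), 1.0 - PMIN)
        b0c = np.log(pc / (1.0 - pc))
        for l in range(L):
            B[l, 0] = b0c
        return B

    xm = np.zeros(p)
    xs = np.ones(p)
    active = np.ones(p, dtype=np.bool_)
    Z = np.empty((n, p))
    for j in range(p):
        m = X[:, j].mean()
        v = 0.0
        for i in range(n):
            v += (X[i, j] - m) ** 2
        v /= n
        if v <= 1e-12:
            active[j] = False
            xm[j] = m
            xs[j] = 1.0
        elif standardize:
            xm[j] = m
            xs[j] = np.sqrt(v)
        for i in range(n):
            Z[i, j] = (X[i, j] - xm[j]) / xs[j]

    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)

    for l in range(L):
        lam = lambdas[l]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _ in range(_MAX_IRLS):
            # working response and weights at current eta
            pvec = 1.0 / (1.0 + np.exp(-eta))
            w = np.empty(n)
            z = np.empty(n)
            for i in range(n):
                pi = min(max(pvec[i], PMIN), 1.0 - PMIN)
                w[i] = pi * (1.0 - pi)
                z[i] = eta[i] + (y[i] - pi) / w[i]
            r = z - eta  # residual wrt current (b0, beta)
            wsum = w.sum()
            for _ in range(_MAX_CD):
                dmax = 0.0
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                db0 = num / wsum
                if db0 != 0.0:
                    b0 += db0
                    for i in range(n):
                        r[i] -= db0
                    if abs(db0) > dmax:
                        dmax = abs(db0)
                for j in range(p):
                    if not active[j]:
                        continue
                    wz2 = 0.0
                    rho = 0.0
                    for i in range(n):
                        wz2 += w[i] * Z[i, j] * Z[i, j]
                        rho += w[i] * Z[i, j] * r[i]
                    wz2 /= n
                    rho = rho / n + wz2 * beta[j]
                    bj = _soft(rho, l1) / (wz2 + l2)
                    d = bj - beta[j]
                    if d != 0.0:
                        beta[j] = bj
                        for i in range(n):
                            r[i] -= d * Z[i, j]
                        if abs(d) > dmax:
                            dmax = abs(d)
                if dmax < tol:
                    break
            eta_new = z - r
            shift = 0.0
            for i in range(n):
                s = abs(eta_new[i] - eta[i])
                if s > shift:
                    shift = s
            eta = eta_new
            if shift < tol * 10.0:
                break
        # back to original scale
        b0_orig = b0
        for j in range(p):
            B[l, j + 1] = beta[j] / xs[j]
            b0_orig -= beta[j] * xm[j] / xs[j]
        B[l, 0] = b0_orig
    return B


@njit(cache=True)
def loocv_paths(X, y, lambdas, alpha, standardize, tol):
    """Leave-one-out fold coefficients, shape (n, n_lambda, p + 1).

    Fold i is fitted on all samples except i (standardization recomputed
    within the fold); the held-out sample never touches its fold's fit.
    """
    n, p = X.shape
    L = lambdas.shape[0]
    coefs = np.empty((n, L, p + 1))
    Xtr = np.empty((n - 1, p))
    ytr = np.empty(n - 1)
    for i in range(n):
        k = 0
        for r in range(n):
            if r == i:
                continue
            for j in range(p):
                Xtr[k, j] = X[r, j]
            ytr[k] = y[r]
            k += 1
        coefs[i] = fit_path(Xtr, ytr, lambdas, alpha, standardize, tol)
    return coefs
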
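"""Compiled l1-penalized logistic regression path solver.

Minimizes, for each lambda on a decreasing grid,

    (1/n) sum_i [log(1 + exp(eta_i)) - y_i * eta_i] + lambda * sum_j |beta_j|

with an unpenalized intercept, by iteratively reweighted least squares
(IRLS) around the current linear predictor and cyclic coordinate descent
with soft-thresholding on the weighted working response -- the standard
penalized-GLM path algorithm.  Warm starts carry the solution down the
grid, and an ever-active set restricts most sweeps to coordinates that
have entered the model, with periodic full sweeps to catch violators.

Columns of ``XT`` are expected standardized (mean 0, unit population SD);
``XT`` is the (p, n) transpose so coordinate sweeps read contiguous memory.
IRLS weights are floored at 1e-5 for stability near saturated fits.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["logistic_lasso_path", "cv_fold_deviance"]


@njit(cache=False)
def logistic_lasso_path(XT, y, lambdas, tol, max_outer):
    """Solve the full lambda path; returns (intercepts (L,), betas (L, p))."""
    p, n = XT.shape
    L = len(lambdas)
    betas = np.zeros((L, p))
    intercepts = np.zeros(L)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    w = np.empty(n)
    z = np.empty(n)
    r = np.empty(n)
    wx2 = np.empty(p)
    ever_active = np.zeros(p, np.bool_)
    for li in range(L):
        lam = lambdas[li]
        for _outer in range(max_outer):
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = pi * (1.0 - pi)
                if wi < 1e-5:
                    wi = 1e-5
                w[i] = wi
                z[i] = eta[i] + (y[i] - pi) / wi
                r[i] = z[i] - eta[i]
            wsum = 0.0
            for i in range(n):
                wsum += w[i]
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * XT[j, i] * XT[j, i]
                wx2[j] = s / n
            for inner in range(1000):
                full = (inner == 0) or (inner % 5 == 4)
                maxd = 0.0
                g0 = 0.0
                for i in range(n):
                    g0 += w[i] * r[i]
                d0 = g0 / wsum
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0
                    if abs(d0) > maxd:
                        maxd = abs(d0)
                for j in range(p):
                    if not (full or ever_active[j]):
                        continue
                    g = 0.0
                    for i in range(n):
                        g += w[i] * XT[j, i] * r[i]
                    g = g / n + wx2[j] * beta[j]
                    if g > lam:
                        bnew = (g - lam) / wx2[j]
                    elif g < -lam:
                        bnew = (g + lam) / wx2[j]
                    else:
                        bnew = 0.0
                    d = bnew - beta[j]
                    if d != 0.0:
                        beta[j] = bnew
                        ever_active[j] = True
                        for i in range(n):
                            r[i] -= d * XT[j, i]
                        if abs(d) > maxd:
                            maxd = abs(d)
                if maxd < tol and full:
                    break
            etadiff = 0.0
            for i in range(n):
                neweta = z[i] - r[i]
                if abs(neweta - eta[i]) > etadiff:
                    etadiff = abs(neweta - eta[i])
                eta[i] = neweta
            if etadiff < tol * 10.0:
                break
        betas[li] = beta
        intercepts[li] = b0
    return intercepts, betas


@njit(cache=False)
def cv_fold_deviance(X, y, lambdas, folds, nfold, tol, max_outer):
    """Mean held-out binomial deviance per lambda across CV folds.

    Each fold re-standardizes its training rows (population SD) before
    fitting its own path; linear predictors are clipped at +/-30 so the
    deviance stays finite for separated folds.
    """
    n, p = X.shape
    L = len(lambdas)
    dev = np.zeros(L)
    for f in range(nfold):
        ntr = 0
        for i in range(n):
            if folds[i] != f:
                ntr += 1
        nte = n - ntr
        XtrT = np.empty((p, ntr))
        ytr = np.empty(ntr)
        Xte = np.empty((nte, p))
        yte = np.empty(nte)
        a = 0
        b = 0
        for i in range(n):
            if folds[i] != f:
                for j in range(p):
                    XtrT[j, a] = X[i, j]
                ytr[a] = y[i]
                a += 1
            else:
                for j in range(p):
                    Xte[b, j] = X[i, j]
                yte[b] = y[i]
                b += 1
        for j in range(p):
            mu = 0.0
            for i in range(ntr):
                mu += XtrT[j, i]
            mu /= ntr
            s = 0.0
            for i in range(ntr):
                s += (XtrT[j, i] - mu) ** 2
            s = np.sqrt(s / ntr)
            if s <= 0.0:
                s = 1.0
            for i in range(ntr):
                XtrT[j, i] = (XtrT[j, i] - mu) / s
            for i in range(nte):
                Xte[i, j] = (Xte[i, j] - mu) / s
        b0s, Bs = logistic_lasso_path(XtrT, ytr, lambdas, tol, max_outer)
        for li in range(L):
            d = 0.0
            for i in range(nte):
                eta = b0s[li]
                for j in range(p):
                    if Bs[li, j] != 0.0:
                        eta += Bs[li, j] * Xte[i, j]
                if eta > 30.0:
                    eta = 30.0
                elif eta < -30.0:
                    eta = -30.0
                pi = 1.0 / (1.0 + np.exp(-eta))
                d += -2.0 * (yte[i] * np.log(pi) + (1.0 - yte[i]) * np.log(1.0 - pi))
            dev[li] += d / nte
    return dev / nfold
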
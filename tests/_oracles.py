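"""Independent reference implementations used only for cross-checking.

These deliberately avoid the package's own code paths: NIPALS PLS1 with
deflation (vs the package's SIMPLS), explicit normal-equations OLS, a
brute-force leave-one-out loop, an explicit rank-one target projection for
the selectivity ratio, and an F-distribution quantile obtained by
inverting the regularised-incomplete-beta CDF.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special


def autoscale(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def nipals_pls1_predict(X_cal, y_cal, X_new, A):
    """NIPALS PLS1 with X and y deflation; autoscaled X, centred y."""
    mu, sd = X_cal.mean(axis=0), X_cal.std(axis=0, ddof=1)
    Xd = (X_cal - mu) / sd
    Xs_new = (X_new - mu) / sd
    y_mean = y_cal.mean()
    yd = y_cal - y_mean
    W, P, Q = [], [], []
    for _ in range(A):
        w = Xd.T @ yd
        w = w / np.linalg.norm(w)
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q = (yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - t * q
        W.append(w)
        P.append(p)
        Q.append(q)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)
    return Xs_new @ B + y_mean


def ols_predict(X_cal, y_cal, X_new):
    """Least squares of y on autoscaled X plus intercept, via normal equations."""
    mu, sd = X_cal.mean(axis=0), X_cal.std(axis=0, ddof=1)
    Xs = (X_cal - mu) / sd
    beta, *_ = np.linalg.lstsq(Xs, y_cal - y_cal.mean(), rcond=None)
    return (X_new - mu) / sd @ beta + y_cal.mean()


def selectivity_ratio_reference(Xs, b):
    """Explicit rank-one target projection, column by column."""
    t = Xs @ b / np.linalg.norm(b)
    sr = np.empty(Xs.shape[1])
    for j in range(Xs.shape[1]):
        proj_coeff = (t @ Xs[:, j]) / (t @ t)
        explained = proj_coeff * t
        resid = Xs[:, j] - explained
        sr[j] = (explained @ explained) / (resid @ resid)
    return sr


def f_upper_quantile_reference(alpha, d1, d2):
    """Upper-alpha F quantile by inverting the incomplete-beta CDF with brentq."""

    def cdf(x):
        return special.betainc(d1 / 2.0, d2 / 2.0, d1 * x / (d1 * x + d2))

    return optimize.brentq(lambda x: cdf(x) - (1.0 - alpha), 1e-9, 1e6, xtol=1e-10)
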
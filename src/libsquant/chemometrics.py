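"""Core chemometrics: autoscaling, univariate regression, SIMPLS PLS1,
k-fold cross-validation and the r/RMSE performance metrics.

The regression model is partial least squares with de Jong's SIMPLS
algorithm, specialised to a single response (PLS1). Predictors are
autoscaled (mean-centred, divided by the n−1 standard deviation); the
response (adulterant mass fraction) is centred but not scaled. The number
of latent variables is chosen by random k-fold cross-validation as the
global minimiser of RMSECV, ties going to the smaller model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Scaler",
    "PLSModel",
    "UnivariateResult",
    "CVResult",
    "autoscale_fit",
    "autoscale_apply",
    "autoscale_invert",
    "ols_univariate",
    "simpls_fit",
    "pls_predict",
    "kfold_cv",
    "pearson_r",
    "rmse",
]


@dataclass(frozen=True)
class Scaler:
    """Per-variable autoscaling parameters (mean, n−1 standard deviation)."""

    means: np.ndarray
    sds: np.ndarray


def autoscale_fit(X: np.ndarray) -> Scaler:
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.nonzero(sds == 0)[0]
    if zero.size:
        raise ValueError(f"variable {zero[0]} has zero variance; cannot autoscale")
    return Scaler(means=means, sds=sds)


def autoscale_apply(scaler: Scaler, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - scaler.means) / scaler.sds


def autoscale_invert(scaler: Scaler, Xs: np.ndarray) -> np.ndarray:
    return np.asarray(Xs, dtype=float) * scaler.sds + scaler.means


@dataclass(frozen=True)
class UnivariateResult:
    """Least-squares fit of fraction on one peak intensity."""

    slope: float
    intercept: float
    r: float  # signed Pearson correlation; rendered unsigned in reports
    rmse: float


def ols_univariate(x: np.ndarray, y: np.ndarray) -> UnivariateResult:
    """Fit y ≈ a·x + c by ordinary least squares (single predictor)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; univariate fit undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return UnivariateResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass
class PLSModel:
    """Fitted SIMPLS PLS1 model.

    ``R`` (p×A) are the X-weights, ``P`` (p×A) the X-loadings, ``q`` (A,)
    the y-loadings and ``T`` (n×A) the calibration scores, all in the
    autoscaled/centred space. ``b = R q`` is the regression vector in
    scaled space; predictions are ``autoscale(X) · b + y_center``.
    """

    A: int
    R: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    b: np.ndarray
    scaler_X: Scaler
    y_center: float
    fitted: np.ndarray = field(repr=False, default=None)


def _simpls_core(Xs: np.ndarray, yc: np.ndarray, A: int, strict: bool = True):
    """SIMPLS for a single centred response on autoscaled X.

    Iteratively deflates the cross-product s = Xsᵀyc against an orthonormal
    basis of the loading space; each factor's weight is the deflated s.
    With ``strict`` a rank deficiency before A factors raises; otherwise the
    factorization is truncated at the achievable rank.
    """
    n, p = Xs.shape
    tol = 1e-12
    R = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    V = np.zeros((p, A))
    s = Xs.T @ yc
    s_scale = np.linalg.norm(s)
    achieved = A
    for a in range(A):
        r = s.copy()
        t = Xs @ r
        t_norm = np.linalg.norm(t)
        if t_norm <= tol * max(s_scale, 1.0):
            if strict:
                raise np.linalg.LinAlgError(
                    f"rank deficiency at factor {a + 1}: achievable rank is {a}"
                )
            achieved = a
            break
        t /= t_norm
        r /= t_norm
        p_a = Xs.T @ t
        q_a = float(yc @ t)
        v = p_a.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_a)
        v_norm = np.linalg.norm(v)
        if v_norm <= tol * max(np.linalg.norm(p_a), 1.0):
            if strict:
                raise np.linalg.LinAlgError(
                    f"rank deficiency at factor {a + 1}: achievable rank is {a}"
                )
            achieved = a
            break
        v /= v_norm
        s = s - v * (v @ s)
        R[:, a], P[:, a], q[a], T[:, a], V[:, a] = r, p_a, q_a, t, v
    if achieved == 0:
        raise np.linalg.LinAlgError("X carries no covariance with y; rank 0")
    return R[:, :achieved], P[:, :achieved], q[:achieved], T[:, :achieved]


def simpls_fit(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """Autoscale X, centre y, and fit an A-factor SIMPLS PLS1 model."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A must satisfy 1 <= A <= min(n-1, p) = {min(n - 1, p)}")
    scaler = autoscale_fit(X)
    Xs = autoscale_apply(scaler, X)
    y_center = float(y.mean())
    yc = y - y_center
    R, P, q, T = _simpls_core(Xs, yc, A)
    b = R @ q
    return PLSModel(
        A=A, R=R, P=P, q=q, T=T, b=b, scaler_X=scaler,
        y_center=y_center, fitted=Xs @ b + y_center,
    )


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict fractions for raw-unit X_new with a fitted model."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.b.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.b.shape[0]}"
        )
    return autoscale_apply(model.scaler_X, X_new) @ model.b + model.y_center


@dataclass(frozen=True)
class CVResult:
    """Cross-validated latent-variable selection."""

    rmsecv_by_A: np.ndarray  # index a-1 holds RMSECV at a factors
    chosen_A: int
    fold_assignments: np.ndarray
    seed: int
    cv_predictions: np.ndarray = None  # (n, A_max) pooled held-out predictions


def kfold_cv(
    X: np.ndarray, y: np.ndarray, A_max: int = 10, k: int = 10, seed: int = 0
) -> CVResult:
    """Random k-fold CV over factor counts 1..A_max; pick the RMSECV minimiser.

    Each fold's model — including the autoscaler — is refit on the other
    folds only, so no information leaks from held-out samples. A_max is
    capped (with a warning) at the largest count trainable in every fold.
    Ties in RMSECV go to the smaller model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for fi, idx in enumerate(np.array_split(order, k)):
        folds[idx] = fi

    min_train = min(int(np.sum(folds != fi)) for fi in range(k))
    cap = min(min_train - 1, p)
    if A_max > cap:
        warnings.warn(
            f"A_max={A_max} exceeds trainable rank in some fold; capped at {cap}",
            stacklevel=2,
        )
        A_max = cap
    if A_max < 1:
        raise ValueError("no trainable factor count under this fold layout")

    sq_err = np.zeros((A_max, n))
    cv_pred = np.zeros((n, A_max))
    for fi in range(k):
        test = folds == fi
        train = ~test
        scaler = autoscale_fit(X[train])
        Xs_tr = autoscale_apply(scaler, X[train])
        y_center = float(y[train].mean())
        yc_tr = y[train] - y_center
        # non-strict: a numerically rank-deficient fold truncates at its
        # achievable rank and reuses the largest model for higher counts
        R, _, q, _ = _simpls_core(Xs_tr, yc_tr, A_max, strict=False)
        a_fit = R.shape[1]
        Xs_te = autoscale_apply(scaler, X[test])
        for a in range(1, A_max + 1):
            aa = min(a, a_fit)
            pred = Xs_te @ (R[:, :aa] @ q[:aa]) + y_center
            sq_err[a - 1, test] = (pred - y[test]) ** 2
            cv_pred[test, a - 1] = pred

    rmsecv = np.sqrt(sq_err.mean(axis=1))
    chosen_A = int(np.argmin(rmsecv)) + 1  # argmin takes the first (smallest A) on ties
    return CVResult(
        rmsecv_by_A=rmsecv,
        chosen_A=chosen_A,
        fold_assignments=folds,
        seed=seed,
        cv_predictions=cv_pred,
    )


def pearson_r(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape or y_pred.size < 2:
        raise ValueError("inputs must be equal-length vectors with n >= 2")
    if np.ptp(y_pred) == 0 or np.ptp(y_true) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(y_pred, y_true)[0, 1])


def rmse(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.shape != y_true.shape or y_pred.size < 1:
        raise ValueError("inputs must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
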
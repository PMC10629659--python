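"""Partial least squares with jack-knife coefficient inference.

PLS regresses λ on a small number of latent components, which keeps the
fit stable when predictors are collinear or outnumber observations.  With
as many components as (full-rank) predictors it reproduces the
least-squares solution exactly.  The single-response NIPALS deflation is
computed directly (one pass yields the coefficient vector for every
component count, which makes the leave-one-out loops below cheap).
Coefficient standard errors come from leave-one-out refits via the Tukey
jack-knife variance formula, and two-sided p-values from a t distribution
with n-1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, LeaveOneOut

logger = logging.getLogger(__name__)

#: above this sample size component selection switches from leave-one-out
#: to seeded 10-fold cross-validation
_LOO_CUTOFF = 150

_EPS = 1e-12


def _pls1_path(X: np.ndarray, y: np.ndarray, a_max: int) -> np.ndarray:
    """NIPALS PLS1 coefficient path on centered data.

    Returns an (a_max, k) array whose a-th row is the coefficient vector
    of the (a+1)-component model, mapping centered X to centered y.
    Deflation stops early (rows repeat) once X or the y-residual is
    exhausted, e.g. past the rank of X.
    """
    Xd = X - X.mean(axis=0)
    yd = y - y.mean()
    k = X.shape[1]
    W = np.zeros((k, a_max))
    P = np.zeros((k, a_max))
    q = np.zeros(a_max)
    coefs = np.zeros((a_max, k))
    last = np.zeros(k)
    for a in range(a_max):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < _EPS:
            coefs[a:] = last
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < _EPS:
            coefs[a:] = last
            break
        p = Xd.T @ t / tt
        W[:, a], P[:, a], q[a] = w, p, float(yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - q[a] * t
        Wa, Pa = W[:, :a + 1], P[:, :a + 1]
        last = Wa @ np.linalg.solve(Pa.T @ Wa, q[:a + 1])
        coefs[a] = last
    return coefs


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int):
    """PLS regression coefficients of y on X.

    X is expected already standardized (the model surface standardizes,
    and only centering is applied here).  Returns ``(intercept, coefs)``
    on the scale of the inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if not 1 <= n_components <= min(n - 1, k):
        raise ValueError(f"n_components={n_components} outside [1, min(n-1, k)]")
    coefs = _pls1_path(X, y, n_components)[n_components - 1]
    intercept = float(y.mean() - X.mean(axis=0) @ coefs)
    return intercept, coefs


def choose_components(X: np.ndarray, y: np.ndarray, max_components: int = 10,
                      seed: int = 0) -> int:
    """Cross-validated RMSEP minimizer over 1..min(n-1, k, max_components).

    Leave-one-out folds up to n=150 observations, seeded 10-fold beyond
    that.  The winner is the smallest component count whose PRESS lies
    within 1% of the response's total cross-validated sum of squares above
    the minimum: once prediction error saturates, extra components only
    chase noise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < 4:
        raise ValueError("need at least 4 observations")
    a_max = min(n - 1, k, max_components)
    if a_max == 1:
        return 1
    if n <= _LOO_CUTOFF:
        splitter = LeaveOneOut()
    else:
        splitter = KFold(n_splits=10, shuffle=True, random_state=seed)
    press = np.zeros(a_max)
    press0 = 0.0  # intercept-only reference scale
    for tr, te in splitter.split(X):
        a_fold = min(a_max, len(tr) - 1)
        path = _pls1_path(X[tr], y[tr], a_fold)
        x_mean, y_mean = X[tr].mean(axis=0), y[tr].mean()
        press0 += float(np.sum((y[te] - y_mean) ** 2))
        for a in range(a_max):
            b = path[min(a, a_fold - 1)]
            resid = y[te] - (y_mean + (X[te] - x_mean) @ b)
            press[a] += float(resid @ resid)
    # fewest components whose PRESS is within 1% of total CV scatter of the best
    near = np.flatnonzero(press <= press.min() + 0.01 * press0)
    return int(near[0]) + 1


def jackknife_inference(X: np.ndarray, y: np.ndarray, n_components: int,
                        labels=None) -> pd.DataFrame:
    """Leave-one-out jack-knife SEs, t-based p-values and significance stars.

    SE_j = sqrt(((m-1)/m) * sum_i (b_(-i)j - mean_j)^2) over the m = n
    leave-one-out coefficient vectors; t = b_full / SE with m-1 degrees of
    freedom.  A zero SE (perfectly stable coefficient) is reported with
    p = 0 and a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, k = X.shape
    if m < 5:
        raise ValueError("need at least 5 observations for jack-knife inference")
    _, b_full = pls_fit(X, y, n_components)
    loo = np.empty((m, k))
    idx = np.arange(m)
    for i in range(m):
        keep = idx != i
        a = min(n_components, m - 2, k)
        loo[i] = _pls1_path(X[keep], y[keep], a)[a - 1]
    mean_loo = loo.mean(axis=0)
    se = np.sqrt((m - 1) / m * np.sum((loo - mean_loo) ** 2, axis=0))
    zero = se == 0
    if zero.any():
        logger.warning("jackknife: %d coefficient(s) with zero SE; p set to 0",
                       int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, np.inf * np.sign(b_full), b_full / se)
    p = np.where(zero, 0.0, 2.0 * stats.t.sf(np.abs(t), df=m - 1))
    out = pd.DataFrame({
        "coef": b_full, "se": se, "t": t, "p": p,
        "stars": [star_code(v) for v in p],
    })
    if labels is not None:
        out.index = pd.Index(labels, name="variable")
    return out


def star_code(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class PLSInference:
    """Container for a fitted-and-inferred PLS submodel."""
    intercept: float
    table: pd.DataFrame  # coef, se, t, p, stars indexed by variable
    n_components: int
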
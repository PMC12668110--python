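"""Ordinary least squares helpers shared by the scan modules.

Two entry points: :func:`ols_fit` for small joint models (stepwise and
network refits, Eq.-style tests) and :func:`batched_product_ols` for the
genome-wide scans, which solve one 4-parameter model
``y ~ 1 + a_j + b + a_j*b`` per column ``a_j`` against a fixed vector ``b``
via stacked normal equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import t as t_dist


@dataclass
class OLSResult:
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    df_resid: int
    sigma2: float
    cov: np.ndarray
    fitted: np.ndarray
    resid: np.ndarray
    rank: int


def ols_fit(X: np.ndarray, y: np.ndarray) -> OLSResult:
    """OLS with t-based two-sided p-values.

    Raises on rank deficiency; callers that must tolerate collinearity check
    the rank first and drop columns.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise np.linalg.LinAlgError(f"design is rank deficient ({rank} < {k})")
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ y)
    fitted = X @ coef
    resid = y - fitted
    df = n - k
    sigma2 = float(resid @ resid / df) if df > 0 else np.nan
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    p = 2.0 * t_dist.sf(np.abs(tvals), df) if df > 0 else np.full(k, np.nan)
    return OLSResult(coef, se, p, df, sigma2, cov, fitted, resid, rank)


def batched_product_ols(
    y: np.ndarray, b: np.ndarray, A: np.ndarray
) -> dict[str, np.ndarray]:
    """Fit ``y ~ 1 + a_j + b + a_j*b`` for every column a_j of ``A``.

    Returns per-column coefficient/SE/p arrays of shape (m, 4) in the order
    (intercept, a, b, a*b) plus a boolean ``degenerate`` flag.  Degenerate
    columns (zero variance in a_j or in the product) get coef nan and p 1.
    p-values use the t reference with n - 4 residual dof.
    """
    y = np.asarray(y, float)
    b = np.asarray(b, float)
    A = np.asarray(A, float)
    n, m = A.shape
    A2 = A * A
    b2 = b * b

    sa = A.sum(0)
    saa = A2.sum(0)
    sb = b.sum()
    sbb = float(b @ b)
    sab = A.T @ b
    saab = A2.T @ b
    sabb = A.T @ b2
    saabb = A2.T @ b2
    sy = y.sum()
    say = A.T @ y
    sby = float(b @ y)
    saby = A.T @ (b * y)
    yty = float(y @ y)

    M = np.empty((m, 4, 4))
    M[:, 0, 0] = n
    M[:, 0, 1] = M[:, 1, 0] = sa
    M[:, 0, 2] = M[:, 2, 0] = sb
    M[:, 0, 3] = M[:, 3, 0] = sab
    M[:, 1, 1] = saa
    M[:, 1, 2] = M[:, 2, 1] = sab
    M[:, 1, 3] = M[:, 3, 1] = saab
    M[:, 2, 2] = sbb
    M[:, 2, 3] = M[:, 3, 2] = sabb
    M[:, 3, 3] = saabb
    v = np.stack([np.full(m, sy), say, np.full(m, sby), saby], axis=1)

    var_a = saa / n - (sa / n) ** 2
    prod_mean = sab / n
    var_prod = saabb / n - prod_mean**2
    var_b = sbb / n - (sb / n) ** 2
    degenerate = (var_a <= 1e-12) | (var_prod <= 1e-12) | (var_b <= 1e-12)
    # guard collinearity of a with a*b etc. via a scale-relative determinant
    with np.errstate(all="ignore"):
        dets = np.linalg.det(M)
    scale = np.abs(M).max(axis=(1, 2))
    degenerate |= ~np.isfinite(dets) | (np.abs(dets) <= 1e-12 * scale**4)

    coef = np.full((m, 4), np.nan)
    se = np.full((m, 4), np.nan)
    p = np.ones((m, 4))
    ok = ~degenerate
    if ok.any():
        Mok = M[ok]
        vok = v[ok]
        sol = np.linalg.solve(Mok, vok[..., None])[..., 0]
        rss = yty - np.einsum("ij,ij->i", sol, vok)
        df = n - 4
        sigma2 = np.maximum(rss, 0.0) / df
        inv = np.linalg.inv(Mok)
        ses = np.sqrt(np.maximum(sigma2[:, None] * np.einsum("ijj->ij", inv), 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = sol / ses
        pv = 2.0 * t_dist.sf(np.abs(tvals), df)
        coef[ok] = sol
        se[ok] = ses
        p[ok] = pv
    return {"coef": coef, "se": se, "p": p, "degenerate": degenerate, "n": n}
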
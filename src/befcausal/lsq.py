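"""Least-squares core with deterministic rank handling and CR1 clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class RankError(ValueError):
    """Raised when the design matrix is unusable (rank 0 or n <= rank)."""


class ClusterError(ValueError):
    """Raised when clustered inference is requested with fewer than 2 clusters."""


@dataclass
class OLSFit:
    """Result of an ordinary least-squares fit.

    ``coef`` and ``names`` refer to the retained columns only; columns found
    collinear with earlier ones are listed in ``dropped`` (deterministic
    left-to-right order, so re-running the same design gives the same drops).
    """

    coef: np.ndarray
    names: list[str]
    dropped: list[str]
    residuals: np.ndarray
    fitted: np.ndarray
    X: np.ndarray
    xtx_inv: np.ndarray
    rank: int
    n: int

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


def _independent_columns(X: np.ndarray, tol: float) -> list[int]:
    """Left-to-right modified Gram-Schmidt rank screen."""
    n, k = X.shape
    keep: list[int] = []
    Q = np.empty((n, 0))
    for j in range(k):
        v = X[:, j].astype(float)
        norm_v = np.linalg.norm(v)
        if norm_v == 0.0:
            continue
        r = v - Q @ (Q.T @ v)
        r = r - Q @ (Q.T @ r)  # second pass for numerical safety
        norm_r = np.linalg.norm(r)
        if norm_r > tol * norm_v:
            keep.append(j)
            Q = np.hstack([Q, (r / norm_r)[:, None]])
    return keep


def ols(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-9,
) -> OLSFit:
    """Least squares via orthogonal decomposition with collinearity pruning.

    Collinear columns are dropped deterministically left to right, so callers
    should order columns by priority (the variable of interest first).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if len(names) != k:
        raise ValueError("names length does not match number of columns")

    keep = _independent_columns(X, tol)
    if not keep:
        raise RankError("design matrix has rank 0")
    Xk = X[:, keep]
    rank = len(keep)
    if n <= rank:
        raise RankError(f"n={n} observations for rank-{rank} design")

    coef, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    fitted = Xk @ coef
    resid = y - fitted
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    dropped = [names[j] for j in range(k) if j not in keep]
    return OLSFit(
        coef=coef,
        names=[names[j] for j in keep],
        dropped=dropped,
        residuals=resid,
        fitted=fitted,
        X=Xk,
        xtx_inv=xtx_inv,
        rank=rank,
        n=n,
    )


def cluster_robust_vcov(
    X: np.ndarray,
    residuals: np.ndarray,
    clusters: np.ndarray,
    k_total: int | None = None,
) -> np.ndarray:
    """CR1 sandwich covariance.

    ``(X'X)^-1 [sum_g X_g'u_g u_g'X_g] (X'X)^-1`` scaled by
    ``G/(G-1) * (n-1)/(n-k)``.  ``k_total`` may exceed the number of columns
    of ``X`` to account for absorbed fixed-effect degrees of freedom.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    u = np.asarray(residuals, dtype=float).ravel()
    n, k = X.shape
    if k_total is None:
        k_total = k
    codes, uniques = _factorize(clusters)
    G = len(uniques)
    if G < 2:
        raise ClusterError("cluster-robust variance requires at least 2 clusters")
    if n - k_total <= 0:
        raise RankError(f"no residual degrees of freedom (n={n}, k={k_total})")
    S = np.zeros((G, k))
    np.add.at(S, codes, X * u[:, None])
    meat = S.T @ S
    bread = np.linalg.inv(X.T @ X)
    c = (G / (G - 1)) * ((n - 1) / (n - k_total))
    return c * bread @ meat @ bread


def _factorize(values) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd

    codes, uniques = pd.factorize(np.asarray(values))
    return codes, uniques
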
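"""Shared linear-algebra kernels.

All estimators in this package reduce to SVDs and (ridge) least squares;
keeping the kernels here guarantees that reductions between estimators
(e.g. the joint estimator with a zero signal model collapsing onto the
ridge correction) hold exactly, not just numerically.
"""
from __future__ import annotations

import numpy as np

#: relative singular-value threshold below which a direction is treated as null
RANK_TOL = 1e-12


def svd_thin(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD ``a = U @ diag(s) @ Vt`` with non-negative, descending ``s``."""
    return np.linalg.svd(a, full_matrices=False)


def numerical_rank(s: np.ndarray, tol: float = RANK_TOL) -> int:
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > tol * s[0]))


def truncated_svd(a: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-``k`` SVD factors of ``a``.

    For wide matrices (n >> m, the common orientation of expression data)
    the factors are obtained from the m x m Gram matrix, which is much
    cheaper than a full SVD of the m x n array.
    """
    m, n = a.shape
    k = min(k, m, n)
    if n > 4 * m:
        g = a @ a.T
        w, v = np.linalg.eigh(g)
        order = np.argsort(w)[::-1][:k]
        s = np.sqrt(np.clip(w[order], 0.0, None))
        u = v[:, order]
        vt = np.zeros((k, n))
        nz = s > RANK_TOL * (s[0] if s.size and s[0] > 0 else 1.0)
        vt[nz] = (u[:, nz].T @ a) / s[nz, None]
        return u, s, vt
    u, s, vt = svd_thin(a)
    return u[:, :k], s[:k], vt[:k]


def low_rank_approx(a: np.ndarray, p: int) -> np.ndarray:
    """Best rank-``p`` approximation of ``a`` in Frobenius norm."""
    m, n = a.shape
    if p >= min(m, n):
        return a.copy()
    u, s, vt = truncated_svd(a, p)
    return u @ (s[:, None] * vt)


def ridge_solution(
    u: np.ndarray, s: np.ndarray, vt: np.ndarray, nu: float, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge coefficients and fitted values against ``W = U diag(s) Vt``.

    Returns ``(alpha, W @ alpha)`` for ``alpha = (W'W + nu I)^{-1} W'Y``.
    The fitted values shrink each singular direction by s^2/(s^2 + nu),
    so they are exact even when W is rank deficient.
    """
    uy = u.T @ y
    with np.errstate(invalid="ignore"):
        alpha = vt.T @ ((s / (s**2 + nu))[:, None] * uy)
    removed = u @ ((s**2 / (s**2 + nu))[:, None] * uy)
    return alpha, removed


def canonical_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Canonical correlations between the column sets of ``a`` and ``b``.

    Classical CCA: columns are mean-centered, each block is orthonormalized,
    and the singular values of the cross product are returned (descending,
    clipped to [0, 1]).
    """
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    qa, _ = np.linalg.qr(ac)
    qb, _ = np.linalg.qr(bc)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def principal_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Principal angles (radians) between the column spans of two matrices."""
    qa, _ = np.linalg.qr(a)
    qb, _ = np.linalg.qr(b)
    s = np.clip(np.linalg.svd(qa.T @ qb, compute_uv=False), -1.0, 1.0)
    return np.arccos(s)
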
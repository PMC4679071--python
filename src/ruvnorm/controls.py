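"""Correction using negative control genes.

Control genes are assumed unaffected by the factor of interest (their rows
of beta are zero), so the control-gene submatrix Y_c = W alpha_c + eps_c
carries the unwanted factors in its left singular vectors. The factor
estimate W_hat is the truncated SVD factor P E_k of Y_c; removal is either
an ordinary regression of Y on W_hat (naive correction, which annihilates
all variance along the estimated directions) or a ridge regression
(random-loading correction, which shrinks direction i by s_i^2/(s_i^2+nu)
and therefore interpolates between removing nothing and removing all).
"""
from __future__ import annotations

import warnings

import numpy as np

from ._linalg import numerical_rank, ridge_solution, svd_thin
from .data import ControlGeneSet, CorrectionResult, ExpressionMatrix, UnwantedFactors

SCALINGS = ("singular", "unit", "normalized")


def default_k(m: int, n_controls: int) -> int:
    """Rank heuristic for fixed-effect removal: about m/4, capped by the controls."""
    return max(1, min(round(m / 4), n_controls))


def estimate_W_controls(
    Y: ExpressionMatrix,
    controls: ControlGeneSet,
    k: int | None = None,
    center: bool = True,
    scaling: str = "singular",
) -> UnwantedFactors:
    """Estimate unwanted factors from the control-gene submatrix.

    Parameters
    ----------
    Y
        Expression matrix (samples x genes, log scale).
    controls
        Negative-control genes; must be a subset of ``Y.gene_ids``.
    k
        Number of factors. Defaults to ``min(round(m/4), n_controls)``.
    center
        Subtract each control gene's mean across samples before the SVD.
        Appropriate when genes have baseline expression offsets (real
        data); mean-free simulated data are better left uncentered.
    scaling
        Column scaling of the returned factors: ``"singular"`` keeps the
        singular values (P E_k; the default, which makes ridge shrinkage
        differential across directions), ``"unit"`` returns orthonormal
        columns (P), ``"normalized"`` divides P E_k by sqrt(n_controls)
        so the factor covariance approximates the control-gene covariance.
    """
    if scaling not in SCALINGS:
        raise ValueError(f"unknown scaling {scaling!r}; expected one of {SCALINGS}")
    idx = controls.indices(Y)
    yc = Y.values[:, idx]
    if center:
        yc = yc - yc.mean(axis=0)
    if not np.any(yc):
        raise ValueError("control-gene submatrix is identically zero")
    if k is None:
        k = default_k(Y.m, len(idx))
    if not 1 <= k <= min(Y.m, len(idx)):
        raise ValueError(f"need 1 <= k <= min(m, n_controls) = {min(Y.m, len(idx))}")
    u, s, _ = svd_thin(yc)
    rank = numerical_rank(s)
    if k > rank:
        warnings.warn(
            f"k={k} exceeds the rank {rank} of the control submatrix; using k={rank}",
            stacklevel=2,
        )
        k = rank
    w = u[:, :k] * s[:k]
    if scaling == "unit":
        w = u[:, :k].copy()
    elif scaling == "normalized":
        w = w / np.sqrt(len(idx))
    return UnwantedFactors(w, source="control_genes", sample_ids=list(Y.sample_ids))


def naive_correct(Y: ExpressionMatrix, W: UnwantedFactors) -> CorrectionResult:
    """Remove all variance along W by ordinary least squares (projection)."""
    wm = W.W
    u, s, vt = svd_thin(wm)
    if numerical_rank(s, tol=1e-10) < wm.shape[1]:
        raise ValueError(
            "W is rank deficient; reduce k or use ridge_correct, which handles "
            "degenerate directions by shrinkage"
        )
    uy = u.T @ Y.values
    alpha = vt.T @ (uy / s[:, None])
    removed = u @ uy
    return CorrectionResult(
        corrected=Y.with_values(Y.values - removed),
        W_hat=W,
        alpha_hat=alpha,
        nu=0.0,
    )


def ridge_correct(Y: ExpressionMatrix, W: UnwantedFactors, nu: float) -> CorrectionResult:
    """Remove unwanted variation by ridge regression against W.

    Solves ``min_alpha ||Y - W alpha||_F^2 + nu ||alpha||_F^2``; the fitted
    unwanted component shrinks singular direction i of W by
    ``s_i^2 / (s_i^2 + nu)``. Use :func:`naive_correct` for the nu -> 0
    projection limit.
    """
    if nu <= 0:
        raise ValueError("nu must be positive; use naive_correct for nu=0")
    u, s, vt = svd_thin(W.W)
    alpha, removed = ridge_solution(u, s, vt, nu, Y.values)
    return CorrectionResult(
        corrected=Y.with_values(Y.values - removed),
        W_hat=W,
        alpha_hat=alpha,
        nu=float(nu),
    )


def default_nu_grid(W: UnwantedFactors) -> list[float]:
    """Candidate ridge weights: powers of ten of the largest eigenvalue of W'W.

    Returns the eight values ``10^j * lambda_max`` for j = -6..1, ascending
    (weak to strong shrinkage). The appropriate power is data dependent and
    should be picked with diagnostics such as RLE plots or recovery of a
    known positive control.
    """
    s = np.linalg.svd(W.W, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        raise ValueError("W is identically zero")
    lmax = float(s[0] ** 2)
    return [10.0**j * lmax for j in range(-6, 2)]
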
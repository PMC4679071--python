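"""Correction using replicate samples.

Replicates are repeated measurements of the same material, so a difference
of two replicates has a zero row of X: it is a negative "control sample"
that carries only unwanted variation and noise, Y_d = W_d alpha + eps_d.
The three-step algorithm estimates alpha from the truncated SVD of the
difference matrix, estimates W by regressing the control-gene columns of Y
on alpha_hat, and removes W_hat alpha_hat from Y. The factor of interest is
never used: the procedure is fully unsupervised and, by construction,
insensitive to confounding between X and W.
"""
from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from itertools import combinations

from ._linalg import numerical_rank, svd_thin
from .data import (
    ControlGeneSet,
    CorrectionResult,
    ExpressionMatrix,
    ReplicateDesign,
    UnwantedFactors,
)

SCHEMES = ("pairwise", "vs_group_mean")


@dataclass
class DifferenceMatrix:
    """Replicate-difference rows (artificial control samples)."""

    values: np.ndarray
    scheme: str
    row_labels: list[str]
    gene_ids: list[str]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def build_differences(
    Y: ExpressionMatrix, design: ReplicateDesign, scheme: str = "vs_group_mean"
) -> DifferenceMatrix:
    """Form replicate-difference rows per group.

    ``pairwise`` emits one row per unordered pair within a group (each pair
    once); ``vs_group_mean`` emits one row per replicate, the replicate
    minus the mean of the other replicates in its group. For groups of two
    the schemes coincide up to duplication of the sign-flipped row.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if len(design) == 0:
        raise ValueError("replicate design contains no groups")
    rows, labels = [], []
    for gid, members in design.groups.items():
        if len(members) < 2:
            raise ValueError(f"replicate group {gid!r} has fewer than 2 members")
        idx = Y.sample_indices(members)
        block = Y.values[idx]
        if scheme == "pairwise":
            for a, b in combinations(range(len(members)), 2):
                rows.append(block[a] - block[b])
                labels.append(f"{gid}:{members[a]}-{members[b]}")
        else:
            for a in range(len(members)):
                others = np.delete(np.arange(len(members)), a)
                rows.append(block[a] - block[others].mean(axis=0))
                labels.append(f"{gid}:{members[a]}-mean")
    return DifferenceMatrix(
        np.array(rows), scheme=scheme, row_labels=labels, gene_ids=list(Y.gene_ids)
    )


def estimate_alpha_from_differences(D: DifferenceMatrix, k: int) -> np.ndarray:
    """Estimate alpha (k x n) as the scaled top right singular vectors of Y_d.

    The rank-k matrix closest to Y_d in Frobenius norm is P E_k Q'; its row
    factor E_k Q' serves as alpha_hat.
    """
    if not np.any(D.values):
        raise ValueError(
            "replicate differences are identically zero: replicates carry no "
            "unwanted variation"
        )
    _, s, vt = svd_thin(D.values)
    rank = numerical_rank(s)
    if not 1 <= k <= rank:
        raise ValueError(f"need 1 <= k <= rank(D) = {rank}, got k={k}")
    return s[:k, None] * vt[:k]


def estimate_W_replicates(
    Y: ExpressionMatrix,
    controls: ControlGeneSet | None,
    alpha_hat: np.ndarray,
    center: bool = False,
) -> UnwantedFactors:
    """Estimate W by regressing control-gene columns of Y on alpha_hat.

    ``W_r = Y_c alpha_c' (alpha_c alpha_c')^{-1}``. With ``controls=None``
    every gene is used as a control (the extreme all-genes variant, which
    is often competitive because beta-related contamination averages out
    over many genes).
    """
    alpha_hat = np.atleast_2d(np.asarray(alpha_hat, dtype=float))
    if controls is None:
        yc = Y.values
        ac = alpha_hat
    else:
        idx = controls.indices(Y)
        yc = Y.values[:, idx]
        ac = alpha_hat[:, idx]
    if center:
        yc = yc - yc.mean(axis=0)
    s = np.linalg.svd(ac, compute_uv=False)
    if numerical_rank(s, tol=1e-10) < ac.shape[0]:
        raise ValueError(
            "alpha_hat restricted to the control genes is rank deficient; "
            "use a smaller k or a larger control set"
        )
    w = np.linalg.solve(ac @ ac.T, ac @ yc.T).T
    return UnwantedFactors(w, source="replicates", sample_ids=list(Y.sample_ids))


def default_k_replicates(m: int, n_differences: int) -> int:
    """Rank heuristic: about m/4, capped by the number of difference rows."""
    return max(1, min(round(m / 4), n_differences))


def replicate_correct(
    Y: ExpressionMatrix,
    design: ReplicateDesign,
    controls: ControlGeneSet | None = None,
    k: int | None = None,
    scheme: str = "vs_group_mean",
    center: bool = False,
) -> CorrectionResult:
    """Full three-step replicate-based correction of Y.

    The corrected matrix covers every sample (replicates included); the
    difference rows are used only to estimate alpha.
    """
    D = build_differences(Y, design, scheme=scheme)
    if k is None:
        k = default_k_replicates(Y.m, D.n_rows)
    alpha = estimate_alpha_from_differences(D, k)
    W = estimate_W_replicates(Y, controls, alpha, center=center)
    return CorrectionResult(
        corrected=Y.with_values(Y.values - W.W @ alpha),
        W_hat=W,
        alpha_hat=alpha,
        nu=0.0,
    )
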
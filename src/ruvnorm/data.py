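"""Core containers for expression data and correction results.

The package works on log-scale expression matrices with samples in rows and
genes in columns (``Y`` is m x n). Identifiers are carried alongside the
numeric payload so that subsetting, replicate designs and control-gene sets
can be specified by name.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """Samples-by-genes numeric matrix of log-scale expression."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-d array")
        m, n = self.values.shape
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} rows")
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} columns")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.gene_ids, "gene ids")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return np.array([lookup[g] for g in ids], dtype=int)

    def sample_indices(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def restrict_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_indices(ids)
        return ExpressionMatrix(self.values[idx], list(ids), list(self.gene_ids))

    def restrict_genes(self, ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indices(ids)
        return ExpressionMatrix(self.values[:, idx], list(self.sample_ids), list(ids))

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.sample_ids), list(self.gene_ids))


@dataclass
class ControlGeneSet:
    """Genes asserted to be unaffected by the factor of interest (beta = 0)."""

    gene_ids: tuple[str, ...]

    def __init__(self, gene_ids: Iterable[str]):
        self.gene_ids = tuple(str(g) for g in gene_ids)
        _check_unique(self.gene_ids, "control gene ids")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def indices(self, matrix: ExpressionMatrix) -> np.ndarray:
        if not self.gene_ids:
            raise ValueError("control gene set is empty")
        return matrix.gene_indices(self.gene_ids)

    def complement(self, matrix: ExpressionMatrix) -> "ControlGeneSet":
        mine = set(self.gene_ids)
        return ControlGeneSet(g for g in matrix.gene_ids if g not in mine)


@dataclass
class ReplicateDesign:
    """Partition of a subset of samples into replicate groups.

    Samples inside a group are repeated measurements of the same biological
    material: they share the (unobserved) factor of interest, so their
    differences carry only unwanted variation and noise.
    """

    groups: dict[str, tuple[str, ...]]

    def __init__(self, groups: Mapping[str, Iterable[str]]):
        self.groups = {str(k): tuple(str(s) for s in v) for k, v in groups.items()}
        all_ids = [s for members in self.groups.values() for s in members]
        _check_unique(all_ids, "replicate sample ids (groups must be disjoint)")

    @property
    def sample_ids(self) -> list[str]:
        return [s for members in self.groups.values() for s in members]

    def __len__(self) -> int:
        return len(self.groups)


@dataclass
class UnwantedFactors:
    """Estimated unwanted-factor matrix W (m x k)."""

    W: np.ndarray
    source: str  # control_genes | replicates | residual_update | known
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.W.ndim != 2:
            raise ValueError("W must be 2-d")
        m, k = self.W.shape
        if not 1 <= k <= m:
            raise ValueError(f"need 1 <= k <= m, got k={k}, m={m}")
        if self.sample_ids is not None and len(self.sample_ids) != m:
            raise ValueError("sample_ids length does not match W rows")

    @property
    def k(self) -> int:
        return self.W.shape[1]


@dataclass
class CorrectionResult:
    """A corrected matrix Y - W_hat @ alpha_hat together with the estimates."""

    corrected: ExpressionMatrix
    W_hat: UnwantedFactors
    alpha_hat: np.ndarray
    nu: float
    objective_trace: tuple[float, ...] = ()
    xbeta_hat: np.ndarray | None = None

    @property
    def removed(self) -> np.ndarray:
        """The unwanted component W_hat @ alpha_hat that was subtracted."""
        return self.W_hat.W @ self.alpha_hat
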
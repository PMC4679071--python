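"""Metrics, diagnostics and baselines.

Contains the normalized reconstruction error used on simulated data, the
squared partition distance used to compare clusterings, RLE diagnostics,
variance filtering, PCA scores, the quantile-normalization and known-batch
centering baselines, and the driver that reproduces the benchmark table of
correction methods across confounding regimes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._linalg import svd_thin
from .controls import estimate_W_controls, naive_correct, ridge_correct
from .data import ControlGeneSet, ExpressionMatrix
from .replicates import replicate_correct
from .simulate import SimulatedDataset, SimulationConfig, generate_dataset


# ---------------------------------------------------------------------------
# partitions

@dataclass
class Partition:
    """Assignment of samples to clusters (labels are arbitrary symbols)."""

    assignment: dict[str, Hashable]

    @classmethod
    def from_labels(cls, sample_ids: Sequence[str], labels: Sequence[Hashable]) -> "Partition":
        if len(sample_ids) != len(labels):
            raise ValueError("sample_ids and labels differ in length")
        return cls(dict(zip((str(s) for s in sample_ids), labels)))

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[Hashable, set[str]]:
        out: dict[Hashable, set[str]] = {}
        for s, c in self.assignment.items():
            out.setdefault(c, set()).add(s)
        return out


def clustering_distance(c1: Partition, c2: Partition, k: int) -> float:
    """Squared distance between two partitions into k clusters.

    d(C, C') = k - sum_ij |c_i ∩ c'_j|^2 / (|c_i| |c'_j|); zero iff the
    partitions are equivalent up to relabeling, at most k - 1.
    """
    if set(c1.assignment) != set(c2.assignment):
        raise ValueError("partitions cover different sample sets")
    cl1, cl2 = c1.clusters(), c2.clusters()
    if len(cl1) != k or len(cl2) != k:
        raise ValueError(
            f"both partitions must have exactly {k} non-empty clusters "
            f"(got {len(cl1)} and {len(cl2)})"
        )
    total = 0.0
    for a in cl1.values():
        for b in cl2.values():
            inter = len(a & b)
            if inter:
                total += inter * inter / (len(a) * len(b))
    return float(k - total)


# ---------------------------------------------------------------------------
# reconstruction error on simulated data

def reconstruction_error(corrected: ExpressionMatrix, truth: SimulatedDataset) -> float:
    """Normalized reconstruction error against the simulated ground truth.

    ``||(Y - What ahat) - (Y - W alpha)||_F^2 / ||Y - W alpha||_F^2``
    evaluated over the samples present in ``corrected`` (which may be a
    subset of the generated rows, e.g. the main block only). Zero means
    the correction removed exactly the unwanted component.
    """
    if corrected.gene_ids != truth.Y.gene_ids:
        raise ValueError("corrected matrix and truth carry different genes")
    rows = truth.Y.sample_indices(corrected.sample_ids)
    signal = truth.signal[rows]
    den = float(np.sum(signal**2))
    if den == 0.0:
        raise ValueError("ground-truth signal is identically zero")
    return float(np.sum((corrected.values - signal) ** 2)) / den


# ---------------------------------------------------------------------------
# diagnostics and baselines

def variance_filter(Y: ExpressionMatrix, n_keep: int) -> ExpressionMatrix:
    """Keep the n_keep genes with largest sample variance (ties: gene-id order)."""
    if not 1 <= n_keep <= Y.n:
        raise ValueError(f"need 1 <= n_keep <= {Y.n}")
    var = Y.values.var(axis=0, ddof=1)
    order = sorted(range(Y.n), key=lambda j: (-var[j], Y.gene_ids[j]))
    keep = sorted(order[:n_keep])
    return ExpressionMatrix(
        Y.values[:, keep], list(Y.sample_ids), [Y.gene_ids[j] for j in keep]
    )


def compute_rle(Y: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Relative log expression: deviation from each gene's median across samples.

    Returns the RLE matrix and per-sample median / interquartile-range
    summaries. Boxes far from zero or with large spread flag samples still
    driven by unwanted variation.
    """
    rle = Y.values - np.median(Y.values, axis=0)
    q1, med, q3 = np.percentile(rle, [25, 50, 75], axis=1)
    summary = pd.DataFrame(
        {"median": med, "iqr": q3 - q1}, index=pd.Index(Y.sample_ids, name="sample")
    )
    return Y.with_values(rle), summary


def quantile_normalize(Y: ExpressionMatrix) -> ExpressionMatrix:
    """Full-quantile normalization: every sample gets the mean order statistics."""
    v = Y.values
    ref = np.sort(v, axis=1).mean(axis=0)
    ranks = rankdata(v, axis=1, method="average")
    out = np.interp(ranks, np.arange(1, v.shape[1] + 1), ref)
    return Y.with_values(out)


def center_by_batch(Y: ExpressionMatrix, batch: Mapping[str, Hashable]) -> ExpressionMatrix:
    """Subtract per-batch gene-wise means (centering by a known unwanted factor)."""
    missing = [s for s in Y.sample_ids if s not in batch]
    if missing:
        raise ValueError(f"samples without a batch level: {missing[:5]}")
    levels = np.array([batch[s] for s in Y.sample_ids], dtype=object)
    out = Y.values.copy()
    for lev in pd.unique(levels):
        rows = np.where(levels == lev)[0]
        out[rows] -= out[rows].mean(axis=0)
    return Y.with_values(out)


def cluster_samples(
    Y: ExpressionMatrix, k: int, seed: int = 0, n_init: int = 10
) -> Partition:
    """Seeded multi-restart k-means over samples."""
    if k >= Y.m:
        raise ValueError("need fewer clusters than samples")
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Y.values)
    return Partition.from_labels(Y.sample_ids, [int(c) for c in km.labels_])


def pca_scores(Y: ExpressionMatrix, n_components: int) -> np.ndarray:
    """Principal-component scores (U S of the gene-centered matrix).

    Signs are fixed so the largest-magnitude loading of each component is
    positive, making scores reproducible across runs.
    """
    if n_components > min(Y.shape):
        raise ValueError("n_components exceeds min(m, n)")
    centered = Y.values - Y.values.mean(axis=0)
    u, s, vt = svd_thin(centered)
    signs = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return (u * s * signs)[:, :n_components]


def clustering_error_curve(
    Y: ExpressionMatrix,
    reference: Partition,
    k: int,
    n_keep_grid: Iterable[int],
    seed: int = 0,
) -> pd.Series:
    """Partition distance to a reference clustering vs genes retained.

    For each grid value, keeps the highest-variance genes, clusters the
    samples with k-means and measures the distance to the reference
    partition.
    """
    out = {}
    for n_keep in n_keep_grid:
        filtered = variance_filter(Y, n_keep)
        part = cluster_samples(filtered, k, seed=seed)
        out[n_keep] = clustering_distance(part, reference, k)
    return pd.Series(out, name="clustering_distance").rename_axis("n_genes")


# ---------------------------------------------------------------------------
# benchmark-table harness

def harness_nu(cfg: SimulationConfig) -> float:
    """Ridge weight implied by the generating hyperparameters.

    The generator normalizes factor columns to unit norm, so the natural
    scale for the prior on alpha is the aggregate row norm rather than a
    per-entry variance; the noise-to-signal ratio sigma2_eps / sigma2_alpha
    expressed on that scale is nu = n * sigma2_eps / sigma2_alpha.
    """
    return cfg.n * cfg.sigma2_eps / cfg.sigma2_alpha


def _main_block(ds: SimulatedDataset) -> ExpressionMatrix:
    return ds.Y.restrict_samples(ds.main_sample_ids)


def _controls(ds: SimulatedDataset, poor: bool) -> ControlGeneSet:
    good = ds.control_genes
    return good.complement(ds.Y) if poor else good


def _correct_naive(ds: SimulatedDataset, poor: bool = False) -> ExpressionMatrix:
    ym = _main_block(ds)
    w = estimate_W_controls(ym, _controls(ds, poor), k=ds.config.k, center=False)
    return naive_correct(ym, w).corrected


def _correct_ridge(ds: SimulatedDataset, poor: bool = False) -> ExpressionMatrix:
    ym = _main_block(ds)
    ctl = _controls(ds, poor)
    k = min(ym.m, len(ctl))
    w = estimate_W_controls(ym, ctl, k=k, center=False)
    return ridge_correct(ym, w, harness_nu(ds.config)).corrected


def _correct_replicates(ds: SimulatedDataset, poor: bool = False) -> ExpressionMatrix:
    res = replicate_correct(
        ds.Y, ds.replicate_design, controls=_controls(ds, poor), k=ds.config.k
    )
    return res.corrected.restrict_samples(ds.main_sample_ids)


def _correct_batch_center(ds: SimulatedDataset) -> ExpressionMatrix:
    ym = _main_block(ds)
    mapping = dict(zip(ds.Y.sample_ids, (int(b) for b in ds.batch)))
    return center_by_batch(ym, mapping)


TABLE1_METHODS: dict[str, Callable[[SimulatedDataset], ExpressionMatrix]] = {
    "uncorrected": _main_block,
    "quantile_normalization": lambda ds: quantile_normalize(_main_block(ds)),
    "batch_centering": _correct_batch_center,
    "naive": _correct_naive,
    "naive_poor_controls": lambda ds: _correct_naive(ds, poor=True),
    "random_effect": _correct_ridge,
    "random_effect_poor_controls": lambda ds: _correct_ridge(ds, poor=True),
    "replicates": _correct_replicates,
    "replicates_poor_controls": lambda ds: _correct_replicates(ds, poor=True),
}


def run_table1(
    n_seeds: int = 5,
    regimes: Sequence[str] = ("independent", "confounded"),
    base_config: SimulationConfig | None = None,
    methods: Sequence[str] | None = None,
    seed0: int = 0,
) -> pd.DataFrame:
    """Reconstruction-error benchmark of the correction methods.

    Generates ``n_seeds`` datasets per confounding regime, applies each
    method on the main sample block (the replicate block only feeds the
    replicate estimator) and reports the mean and standard error of the
    normalized reconstruction error. Returns a DataFrame indexed by method
    with one (mean, se) column pair per regime.
    """
    base = base_config if base_config is not None else SimulationConfig()
    names = list(methods) if methods is not None else list(TABLE1_METHODS)
    unknown = [n for n in names if n not in TABLE1_METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    columns: dict[tuple[str, str], list[float]] = {}
    for regime in regimes:
        errs: dict[str, list[float]] = {n: [] for n in names}
        for s in range(n_seeds):
            cfg = dataclasses.replace(base, regime=regime, seed=seed0 + s)
            ds = generate_dataset(cfg)
            for name in names:
                corrected = TABLE1_METHODS[name](ds)
                errs[name].append(reconstruction_error(corrected, ds))
        for name in names:
            vals = np.array(errs[name])
            columns[(regime, "mean")] = columns.get((regime, "mean"), []) + [vals.mean()]
            se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            columns[(regime, "se")] = columns.get((regime, "se"), []) + [se]
    return pd.DataFrame(columns, index=pd.Index(names, name="method"))
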
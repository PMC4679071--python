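"""Synthetic expression data with planted wanted and unwanted variation.

The generator produces matrices that follow the factor model

    Y = X beta + W alpha + eps

where X holds the (unobserved) factors of interest -- a binary clinical
grouping, think ER status, plus an associated exponential survival time --
and W holds the unwanted factors: a binary technical platform and a
continuous, normally distributed RNA-quality score. Factor columns are
rescaled to unit Euclidean norm over the main samples, loadings are iid
Gaussian, and a configurable number of extra biological samples is appended
with replicated measurements (same X row, freshly drawn W rows) so that
replicate-difference estimators can be exercised.

Three confounding regimes control the dependence between X and W:
``independent`` (separate draws; canonical correlations of order 1/sqrt(m)),
``confounded`` (W is set equal to X; canonical correlations (1, 1)), and
``moderate`` (each W column is a normalized convex mixture of the matching
X column and an independent draw).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from ._linalg import canonical_correlations
from .data import ControlGeneSet, ExpressionMatrix, ReplicateDesign

REGIMES = ("independent", "confounded", "moderate")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data protocol.

    Defaults reproduce the canned study conditions: 100 samples, 10 000
    genes, 100 negative-control genes, unit loading variances, noise
    variance 0.01, survival rates 0.05 (binary group positive) and 0.1,
    and 10 extra samples with 2 replicates each.
    """

    m: int = 100
    n: int = 10_000
    n_controls: int = 100
    sigma2_eps: float = 0.01
    sigma2_alpha: float = 1.0
    sigma2_beta: float = 1.0
    rate_pos: float = 0.05
    rate_neg: float = 0.1
    regime: str = "independent"
    mixing: float | tuple[float, float] = 0.5
    n_replicate_samples: int = 10
    replicates_per_sample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.m < 4:
            raise ValueError("need at least m=4 samples")
        if not 0 <= self.n_controls < self.n:
            raise ValueError("need n > n_controls >= 0")
        for name in ("sigma2_eps", "sigma2_alpha", "sigma2_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rate_pos <= 0 or self.rate_neg <= 0:
            raise ValueError("exponential rates must be positive")
        for g in self.mixing_pair:
            if not 0.0 <= g <= 1.0:
                raise ValueError("mixing must lie in [0, 1]")
        if self.n_replicate_samples < 0:
            raise ValueError("n_replicate_samples must be >= 0")
        if self.n_replicate_samples > 0 and self.replicates_per_sample < 2:
            raise ValueError("replicates_per_sample must be >= 2")

    @property
    def mixing_pair(self) -> tuple[float, float]:
        if np.isscalar(self.mixing):
            return (float(self.mixing), float(self.mixing))
        g1, g2 = self.mixing  # type: ignore[misc]
        return (float(g1), float(g2))

    @property
    def p(self) -> int:
        return 2

    @property
    def k(self) -> int:
        return 2


@dataclass
class SimulatedDataset:
    """A generated dataset together with its ground truth."""

    Y: ExpressionMatrix
    X: np.ndarray
    beta: np.ndarray
    W: np.ndarray
    alpha: np.ndarray
    eps: np.ndarray
    control_mask: np.ndarray
    replicate_design: ReplicateDesign
    batch: np.ndarray
    config: SimulationConfig

    @property
    def main_sample_ids(self) -> list[str]:
        return self.Y.sample_ids[: self.config.m]

    @property
    def control_genes(self) -> ControlGeneSet:
        return ControlGeneSet(
            g for g, c in zip(self.Y.gene_ids, self.control_mask) if c
        )

    @property
    def signal(self) -> np.ndarray:
        """The target of correction, Y - W alpha = X beta + eps."""
        return self.X @ self.beta + self.eps


def _draw_nonconstant_binary(rng: np.random.Generator, size: int) -> np.ndarray:
    """Fair-coin 0/1 vector, redrawn in the rare event of a constant draw."""
    if size == 1:
        return (rng.random(1) < 0.5).astype(float)
    for _ in range(1000):
        b = (rng.random(size) < 0.5).astype(float)
        if 0 < b.sum() < size:
            return b
    raise RuntimeError("could not draw a non-constant binary vector")


def _raw_signal_factors(rng: np.random.Generator, size: int, cfg: SimulationConfig) -> np.ndarray:
    group = _draw_nonconstant_binary(rng, size)
    rate = np.where(group > 0, cfg.rate_pos, cfg.rate_neg)
    survival = rng.exponential(1.0 / rate)
    return np.column_stack([group, survival])


def _raw_unwanted_factors(rng: np.random.Generator, size: int) -> np.ndarray:
    platform = _draw_nonconstant_binary(rng, size)
    quality = rng.standard_normal(size)
    return np.column_stack([platform, quality])


def _mix_columns(x: np.ndarray, u: np.ndarray, mixing: tuple[float, float]) -> np.ndarray:
    cols = []
    for j, g in enumerate(mixing):
        col = g * x[:, j] + (1.0 - g) * u[:, j]
        cols.append(col / np.linalg.norm(col))
    return np.column_stack(cols)


def generate_factors(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw unit-norm factor matrices (X, W) for the main samples.

    X column 1 is the binary grouping (0/1 coin before normalization),
    column 2 the exponential survival covariate; W column 1 the binary
    platform, column 2 the Gaussian quality score. The regime determines
    the dependence of W on X.
    """
    xraw = _raw_signal_factors(rng, cfg.m, cfg)
    uraw = _raw_unwanted_factors(rng, cfg.m)
    x = xraw / np.linalg.norm(xraw, axis=0)
    u = uraw / np.linalg.norm(uraw, axis=0)
    if cfg.regime == "independent":
        w = u
    elif cfg.regime == "confounded":
        w = x.copy()
    else:
        w = _mix_columns(x, u, cfg.mixing_pair)
    return x, w


def generate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset, replicate block included.

    Draws are split over per-component streams derived from ``cfg.seed``
    (factors, replicate factors, loadings, noise), so the same seed always
    reproduces the same dataset bit for bit.
    """
    s_fac, s_rep, s_load, s_noise = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_fac = np.random.default_rng(s_fac)

    xraw = _raw_signal_factors(rng_fac, cfg.m, cfg)
    uraw = _raw_unwanted_factors(rng_fac, cfg.m)
    xnorm = np.linalg.norm(xraw, axis=0)
    unorm = np.linalg.norm(uraw, axis=0)
    x = xraw / xnorm
    u = uraw / unorm
    if cfg.regime == "independent":
        w = u
    elif cfg.regime == "confounded":
        w = x.copy()
    else:
        w = _mix_columns(x, u, cfg.mixing_pair)

    # batch labels for known-unwanted-factor baselines: the binary level of
    # the first unwanted factor actually present in W
    if cfg.regime == "confounded":
        batch_main = xraw[:, 0].astype(int)
    else:
        batch_main = uraw[:, 0].astype(int)

    # replicate block: fresh biological samples, each measured several times;
    # X rows repeat within a group, W rows are drawn fresh per measurement.
    # Raw draws reuse the main-sample normalization constants so replicate
    # rows live on the same scale as the main block.
    rng_rep = np.random.default_rng(s_rep)
    extra_x, extra_w, extra_batch = [], [], []
    groups: dict[str, list[str]] = {}
    sample_ids = [f"sample_{i + 1:03d}" for i in range(cfg.m)]
    for i in range(cfg.n_replicate_samples):
        xrow = _raw_signal_factors(rng_rep, 1, cfg)[0] / xnorm
        gid = f"extra_{i + 1:02d}"
        groups[gid] = []
        for r in range(cfg.replicates_per_sample):
            wraw = _raw_unwanted_factors(rng_rep, 1)[0]
            extra_x.append(xrow)
            extra_w.append(wraw / unorm)
            extra_batch.append(int(wraw[0]))
            sid = f"{gid}_rep{r + 1}"
            groups[gid].append(sid)
            sample_ids.append(sid)
    if extra_x:
        x_all = np.vstack([x, np.array(extra_x)])
        w_all = np.vstack([w, np.array(extra_w)])
    else:
        x_all, w_all = x, w
    batch = np.concatenate([batch_main, np.array(extra_batch, dtype=int)])

    rng_load = np.random.default_rng(s_load)
    beta = rng_load.standard_normal((cfg.p, cfg.n)) * np.sqrt(cfg.sigma2_beta)
    alpha = rng_load.standard_normal((cfg.k, cfg.n)) * np.sqrt(cfg.sigma2_alpha)
    control_mask = np.zeros(cfg.n, dtype=bool)
    control_mask[: cfg.n_controls] = True
    beta[:, control_mask] = 0.0

    rng_noise = np.random.default_rng(s_noise)
    eps = rng_noise.standard_normal((x_all.shape[0], cfg.n)) * np.sqrt(cfg.sigma2_eps)

    values = x_all @ beta + w_all @ alpha + eps
    gene_ids = [f"gene_{j + 1:05d}" for j in range(cfg.n)]
    y = ExpressionMatrix(values, sample_ids, gene_ids)
    design = ReplicateDesign(groups)
    return SimulatedDataset(
        Y=y, X=x_all, beta=beta, W=w_all, alpha=alpha, eps=eps,
        control_mask=control_mask, replicate_design=design, batch=batch, config=cfg,
    )


def mean_canonical_correlations(
    cfg: SimulationConfig, n_seeds: int = 50, seed0: int = 0
) -> np.ndarray:
    """Average canonical correlations between X and W over generator seeds."""
    accum = np.zeros(cfg.p)
    for s in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence(seed0 + s))
        x, w = generate_factors(cfg, rng)
        accum += canonical_correlations(x, w)
    return accum / n_seeds


def calibrate_mixing(
    cfg: SimulationConfig,
    targets: tuple[float, float] = (0.99, 0.8),
    n_seeds: int = 30,
    n_iter: int = 20,
) -> tuple[float, float]:
    """Search per-column mixing weights matching target canonical correlations.

    The construction of the moderate regime is a normalized convex mixture;
    the mean canonical correlations increase monotonically in each weight,
    so a coordinate-wise bisection suffices. This is a calibration helper,
    not an exact inversion: the match is to the Monte-Carlo mean.
    """
    lo = np.zeros(2)
    hi = np.ones(2)
    gamma = np.array([0.5, 0.5])
    for _ in range(n_iter):
        probe = dataclasses.replace(cfg, regime="moderate", mixing=tuple(gamma))
        cc = mean_canonical_correlations(probe, n_seeds=n_seeds)
        for j in range(2):
            if cc[j] < targets[j]:
                lo[j] = gamma[j]
            else:
                hi[j] = gamma[j]
        gamma = (lo + hi) / 2.0
    return (float(gamma[0]), float(gamma[1]))
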
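"""Joint estimation of the signal term and the unwanted loadings.

When some structure is known for the signal term X beta -- cluster means,
low rank, or a sparse dictionary -- alpha and X beta can be estimated
jointly given W by alternating minimization of

    || Y - X beta - W alpha ||_F^2 + nu || alpha ||_F^2 .

Each alpha-step is a ridge regression of the signal-adjusted matrix on W;
each signal-step fits the structured model to Y - W alpha_hat. For signal
models that minimize their subproblem exactly (zero, low rank) every
half-step decreases the objective. Optionally W itself is re-estimated
from the residuals Y - Xbeta_hat on a fixed schedule, in the spirit of
feasible generalized least squares: once a signal estimate exists, the
residuals isolate the unwanted component over all genes rather than only
the controls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._linalg import low_rank_approx, numerical_rank, ridge_solution, svd_thin
from .data import CorrectionResult, ExpressionMatrix, UnwantedFactors

SIGNAL_KINDS = ("zero", "kmeans", "low_rank", "sparse_dictionary")


@dataclass
class SignalModel:
    """Structural model for the signal term X beta.

    kind
        ``zero`` (no signal; the joint fit reduces to the plain ridge
        correction), ``kmeans`` (rows take one of p cluster centroids),
        ``low_rank`` (best rank-p approximation), or ``sparse_dictionary``
        (rank <= p, unit-norm dictionary columns, l1-penalized loadings).
    p
        Cluster count or signal rank.
    lam
        l1 penalty weight (sparse_dictionary only).
    """

    kind: str = "low_rank"
    p: int = 1
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal model {self.kind!r}")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclass
class JointConfig:
    """Iteration schedule and hyperparameters for the alternating fit."""

    n_iter: int = 100
    w_update_every: int = 0
    nu: float = 1.0
    k: int | None = None
    seed: int = 0
    center_w_update: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 <= self.w_update_every <= self.n_iter:
            raise ValueError("w_update_every must lie in {0, ..., n_iter}")
        if self.nu <= 0:
            raise ValueError("nu must be positive")


def _soft_threshold(a: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def _fit_sparse_dictionary(
    r: np.ndarray,
    p: int,
    lam: float,
    rng: np.random.Generator,
    x0: np.ndarray | None = None,
    n_inner: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Local minimizer of 0.5||R - X beta||_F^2 + lam ||beta||_1.

    Constraints: rank(X beta) <= p and unit-ball dictionary columns.
    Alternates a beta-step (per-gene soft thresholding against the
    orthogonalized dictionary) with a normalized least-squares X-step.
    Returns (X beta, X) so callers can warm-start.
    """
    m = r.shape[0]
    if x0 is None:
        x0 = rng.standard_normal((m, p))
        x0 /= np.linalg.norm(x0, axis=0)
    x = x0
    prev = None
    fitted = np.zeros_like(r)
    for _ in range(n_inner):
        q, _ = np.linalg.qr(x)
        b = _soft_threshold(q.T @ r, lam)
        fitted = q @ b
        if not np.any(b):
            return np.zeros_like(r), q
        gram = b @ b.T
        xn = np.linalg.solve(gram + 1e-12 * np.eye(p), b @ r.T).T
        norms = np.maximum(np.linalg.norm(xn, axis=0), 1.0)
        x = xn / norms
        obj = 0.5 * float(np.sum((r - fitted) ** 2)) + lam * float(np.abs(b).sum())
        if prev is not None and abs(prev - obj) <= tol * max(1.0, prev):
            break
        prev = obj
    return fitted, x


def fit_signal(
    r: np.ndarray, model: SignalModel, rng: np.random.Generator
) -> np.ndarray:
    """Fit the structured signal model to a residual matrix ``r``."""
    if model.kind == "zero":
        return np.zeros_like(r)
    if model.kind == "low_rank":
        return low_rank_approx(r, model.p)
    if model.kind == "kmeans":
        if model.p >= r.shape[0]:
            raise ValueError("k-means needs fewer clusters than samples")
        from sklearn.cluster import KMeans

        km = KMeans(
            n_clusters=model.p,
            n_init=10,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(r)
        return km.cluster_centers_[km.labels_]
    fitted, _ = _fit_sparse_dictionary(r, model.p, model.lam, rng)
    return fitted


def reestimate_W_from_residuals(
    Y: ExpressionMatrix, xbeta_hat: np.ndarray, k: int, center: bool = True
) -> UnwantedFactors:
    """Re-estimate W as the scaled top-k left singular factor of Y - Xbeta_hat."""
    r = Y.values - xbeta_hat
    if center:
        r = r - r.mean(axis=0)
    u, s, _ = svd_thin(r)
    rank = numerical_rank(s)
    if k > rank:
        warnings.warn(
            f"k={k} exceeds the residual rank {rank}; using k={rank}", stacklevel=2
        )
        k = rank
    return UnwantedFactors(
        u[:, :k] * s[:k], source="residual_update", sample_ids=list(Y.sample_ids)
    )


def joint_correct(
    Y: ExpressionMatrix,
    W: UnwantedFactors,
    model: SignalModel,
    cfg: JointConfig,
) -> CorrectionResult:
    """Alternating joint fit of (X beta, alpha) given W.

    Records the penalized objective after every half-step; for signal
    models that solve their subproblem exactly the trace is non-increasing
    between W re-estimations. The corrected matrix is Y - W_hat alpha_hat
    (the signal estimate is returned separately as ``xbeta_hat``; it is
    not subtracted).
    """
    yv = Y.values
    wm = W.W
    source = W.source
    u, s, vt = svd_thin(wm)
    rng = np.random.default_rng(cfg.seed)
    xb = np.zeros_like(yv)
    x_warm: np.ndarray | None = None
    trace: list[float] = []

    def objective(alpha: np.ndarray, removed: np.ndarray) -> float:
        return float(np.sum((yv - xb - removed) ** 2) + cfg.nu * np.sum(alpha**2))

    alpha, removed = ridge_solution(u, s, vt, cfg.nu, yv - xb)
    for it in range(1, cfg.n_iter + 1):
        # (a) ridge step in alpha given the current signal estimate
        alpha, removed = ridge_solution(u, s, vt, cfg.nu, yv - xb)
        trace.append(objective(alpha, removed))
        # (b) signal step given the current unwanted estimate
        resid = yv - removed
        if model.kind == "sparse_dictionary":
            xb, x_warm = _fit_sparse_dictionary(
                resid, model.p, model.lam, rng, x0=x_warm
            )
        else:
            xb = fit_signal(resid, model, rng)
        trace.append(objective(alpha, removed))
        if not np.isfinite(trace[-1]):
            raise RuntimeError(
                f"joint estimation diverged at iteration {it} (non-finite objective)"
            )
        if cfg.w_update_every and it % cfg.w_update_every == 0:
            k = cfg.k if cfg.k is not None else wm.shape[1]
            wf = reestimate_W_from_residuals(Y, xb, k, center=cfg.center_w_update)
            wm, source = wf.W, wf.source
            u, s, vt = svd_thin(wm)
    # final ridge step so the returned alpha matches the returned signal
    alpha, removed = ridge_solution(u, s, vt, cfg.nu, yv - xb)
    trace.append(objective(alpha, removed))
    return CorrectionResult(
        corrected=Y.with_values(yv - removed),
        W_hat=UnwantedFactors(wm, source=source, sample_ids=list(Y.sample_ids)),
        alpha_hat=alpha,
        nu=float(cfg.nu),
        objective_trace=tuple(trace),
        xbeta_hat=xb,
    )


def calibrate_lambda(
    Y: ExpressionMatrix,
    W: UnwantedFactors,
    model: SignalModel,
    cfg: JointConfig,
    rel_tol: float = 0.05,
    n_bisect: int = 20,
) -> float:
    """Pick the l1 weight so the removed unwanted energy matches the plain ridge.

    Returns the smallest lambda for which ``||W_hat alpha_hat||_F`` of the
    joint fit is within ``rel_tol`` of the non-iterative ridge correction's,
    making iterative and non-iterative corrections comparable. The norm is
    non-decreasing in lambda (larger penalties push the fit towards the
    zero-signal model), so a bisection applies.
    """
    from .controls import ridge_correct

    if model.kind != "sparse_dictionary":
        raise ValueError("lambda calibration applies to the sparse_dictionary model")
    target = float(np.linalg.norm(ridge_correct(Y, W, cfg.nu).removed))

    def norm_at(lam: float) -> float:
        probe = SignalModel(kind=model.kind, p=model.p, lam=lam)
        return float(np.linalg.norm(joint_correct(Y, W, probe, cfg).removed))

    lo, hi = 0.0, max(1.0, float(np.abs(Y.values).max()))
    while norm_at(hi) < (1.0 - rel_tol) * target:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("lambda calibration failed to bracket the target norm")
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if norm_at(mid) >= (1.0 - rel_tol) * target:
            hi = mid
        else:
            lo = mid
    return hi
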
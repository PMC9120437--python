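"""Stress-minimization embedding of the distance matrix, PCA and correlation.

The N x N Wasserstein matrix is embedded into N points p_i in a low
dimension (default 3) by minimizing the raw stress

    sum_{i<j} (W_ij - ||p_i - p_j||)^2

with simulated annealing (Gaussian point proposals, Metropolis acceptance,
geometric cooling) followed by gradient-descent refinement, over several
random restarts; the restart with the lowest stress wins.  PCA on the
embedded points yields PC1/PC2; PC1 is the candidate affinity-correlated
feature, compared to binding energies by Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import PreconditionError
from .wdist import DistanceMatrix

__all__ = [
    "EmbeddingConfig",
    "EmbeddingResult",
    "FeatureResult",
    "stress",
    "stress_gradient",
    "embed_distances",
    "pca_project",
    "pearson",
]

_EPS = 1e-12


@dataclass(frozen=True)
class EmbeddingConfig:
    """Optimizer settings for the stress embedding.

    The published protocol specifies only "simulated annealing and
    gradient descent" with multiple restarts and 3 dimensions; every
    numeric default here is this package's choice.  The SA temperature
    starts at mean(W)^2 (stress units) and cools geometrically; proposals
    are Gaussian point moves with std sqrt(T).
    """

    dims: int = 3
    n_restarts: int = 32
    sa_initial_temperature: float | None = None  # None -> mean(offdiag W)^2
    sa_cooling_factor: float = 0.995
    sa_steps: int = 2000
    gd_learning_rate: float = 1e-2
    gd_steps: int = 5000
    gd_grad_tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dims < 1 or self.n_restarts < 1:
            raise PreconditionError("dims and n_restarts must be >= 1")
        if not 0 < self.sa_cooling_factor < 1:
            raise PreconditionError("cooling factor must be in (0, 1)")


@dataclass
class EmbeddingResult:
    points: np.ndarray  # (N, dims)
    stress: float
    restart_losses: list[float]


@dataclass
class FeatureResult:
    pc_scores: np.ndarray  # (N, 2)
    explained_variance_fractions: np.ndarray
    loadings: np.ndarray  # (dims, 2)


def _validated(matrix: DistanceMatrix | np.ndarray) -> np.ndarray:
    w = matrix.values if isinstance(matrix, DistanceMatrix) else np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise PreconditionError("distance matrix must be square")
    if not np.allclose(w, w.T):
        raise PreconditionError("distance matrix must be symmetric")
    if np.abs(np.diag(w)).max() > 1e-12:
        raise PreconditionError("distance matrix diagonal must be zero")
    if (w < 0).any():
        raise PreconditionError("distance matrix must be nonnegative")
    return w


def _pairwise_norms(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def stress(points: np.ndarray, matrix: DistanceMatrix | np.ndarray) -> float:
    """Raw stress: sum over i < j of (W_ij - ||p_i - p_j||)^2."""
    w = _validated(matrix)
    points = np.asarray(points, dtype=float)
    if points.shape[0] != w.shape[0]:
        raise PreconditionError(
            f"{points.shape[0]} points for a {w.shape[0]}-system matrix"
        )
    d = _pairwise_norms(points)
    iu = np.triu_indices(w.shape[0], k=1)
    return float(((w[iu] - d[iu]) ** 2).sum())


def stress_gradient(points: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gradient of the stress w.r.t. the points (coincident pairs regularized)."""
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2) + _EPS)
    np.fill_diagonal(d, 1.0)
    coef = -2.0 * (w - d) / d
    np.fill_diagonal(coef, 0.0)
    return (coef[:, :, None] * diff).sum(axis=1)


def _anneal(points, w, rng, t0, cooling, sweeps):
    cur = points.copy()
    cur_stress = _stress_raw(cur, w)
    t = t0
    n = cur.shape[0]
    for _ in range(sweeps):
        sigma = np.sqrt(t)
        for i in range(n):
            proposal = cur[i] + rng.normal(scale=sigma, size=cur.shape[1])
            old = cur[i].copy()
            cur[i] = proposal
            new_stress = _stress_raw(cur, w)
            if new_stress <= cur_stress or rng.uniform() < np.exp(-(new_stress - cur_stress) / max(t, _EPS)):
                cur_stress = new_stress
            else:
                cur[i] = old
        t *= cooling
    return cur, cur_stress


def _stress_raw(points, w):
    d = _pairwise_norms(points)
    iu = np.triu_indices(w.shape[0], k=1)
    return float(((w[iu] - d[iu]) ** 2).sum())


def _descend(points, w, lr, steps, grad_tol):
    """Gradient descent with an adaptive step (halve on increase, grow on success)."""
    cur = points.copy()
    cur_stress = _stress_raw(cur, w)
    step = lr
    for _ in range(steps):
        grad = stress_gradient(cur, w)
        gnorm = float(np.sqrt((grad**2).sum()))
        if gnorm < grad_tol:
            break
        trial = cur - step * grad
        trial_stress = _stress_raw(trial, w)
        if trial_stress < cur_stress:
            cur, cur_stress = trial, trial_stress
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-16:
                break
    return cur, cur_stress


def embed_distances(
    matrix: DistanceMatrix | np.ndarray, config: EmbeddingConfig = EmbeddingConfig()
) -> EmbeddingResult:
    """Best-of-restarts stress embedding of a distance matrix."""
    w = _validated(matrix)
    n = w.shape[0]
    if n < 2:
        raise PreconditionError("need at least 2 systems to embed")
    offdiag = w[np.triu_indices(n, k=1)]
    scale = float(offdiag.mean()) if offdiag.size and offdiag.max() > 0 else 1.0
    t0 = config.sa_initial_temperature if config.sa_initial_temperature is not None else scale**2

    best_points = None
    best_stress = np.inf
    losses = []
    ss = np.random.SeedSequence(config.seed)
    for child in ss.spawn(config.n_restarts):
        rng = np.random.default_rng(child)
        points = rng.normal(scale=scale, size=(n, config.dims))
        points, _ = _anneal(points, w, rng, t0, config.sa_cooling_factor, config.sa_steps)
        points, s = _descend(points, w, config.gd_learning_rate, config.gd_steps, config.gd_grad_tol)
        losses.append(s)
        if s < best_stress:
            best_stress = s
            best_points = points
    return EmbeddingResult(points=best_points, stress=best_stress, restart_losses=losses)


def pca_project(points: np.ndarray, reference_index: int = 0) -> FeatureResult:
    """Top-2 principal components of the embedded points.

    Sign convention: PC1 is oriented so the reference (apo) system scores
    on the negative side; PC2 so its first nonzero loading is positive.
    With fewer than 3 points or collinear configurations PC2 may carry
    zero variance; scores are still returned.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise PreconditionError("need at least 2 points for PCA")
    centered = points - points.mean(axis=0, keepdims=True)
    cov = centered.T @ centered / (points.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    fractions = eigval / total if total > 0 else np.zeros_like(eigval)

    k = min(2, eigvec.shape[1])
    load = np.zeros((points.shape[1], 2))
    load[:, :k] = eigvec[:, :k]
    scores = centered @ load

    if scores[reference_index, 0] > 0:
        scores[:, 0] *= -1
        load[:, 0] *= -1
    nz = np.nonzero(np.abs(load[:, 1]) > 1e-12)[0]
    if nz.size and load[nz[0], 1] < 0:
        scores[:, 1] *= -1
        load[:, 1] *= -1

    frac2 = np.zeros(2)
    frac2[:k] = fractions[:k]
    return FeatureResult(pc_scores=scores, explained_variance_fractions=frac2, loadings=load)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise PreconditionError("pearson needs two equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise PreconditionError("correlation undefined for a constant input")
    return float(stats.pearsonr(x, y).statistic)
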
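"""Two-dimensional Sammon maps of similarity structure and Procrustes
alignment of checkpoint configurations.

The representational trajectory analysis projects each checkpoint's
10x10 correlation matrix into the plane.  Correlations are first turned
into dissimilarities (``d = 1 - r``); the Sammon criterion

    E = (1 / sum_{i<j} delta_ij) * sum_{i<j} (delta_ij - d_ij)^2 / delta_ij

is then minimized over point configurations, where ``delta`` are the
input dissimilarities and ``d`` the embedded Euclidean distances.  The
map is initialized from the classical metric-scaling (Torgerson)
solution and refined with Sammon's diagonal-Newton iteration with step
halving, so the fit is deterministic and its stress never increases
across iterations.  Configurations from different checkpoints are made
visually comparable by similarity Procrustes alignment (translation,
isotropic scale, rotation and reflection) to the end-of-learning map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .rsa import SimilarityMatrix
from .stimuli import CANONICAL_ORDER

__all__ = [
    "DissimilarityMatrix",
    "Configuration2D",
    "to_dissimilarity",
    "sammon_map",
    "sammon_stress",
    "procrustes_align",
    "trajectory",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    values: np.ndarray
    provenance: str = "1 - r"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("dissimilarities must be nonnegative")


@dataclass(frozen=True)
class Configuration2D:
    """A 2-D point configuration with its Sammon stress."""

    points: np.ndarray  # (n, 2)
    stress: float
    n_iter: int = 0
    seed: int | None = None
    checkpoint: int | None = None
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("configuration must be (n, 2)")
        if self.stress < 0:
            raise ValueError("stress must be nonnegative")


def to_dissimilarity(matrix: SimilarityMatrix) -> DissimilarityMatrix:
    """Default correlation-to-dissimilarity transform ``d = 1 - r``."""
    d = 1.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, None)
    return DissimilarityMatrix(values=d, provenance="1 - r")


def sammon_stress(delta: np.ndarray, points: np.ndarray) -> float:
    """Sammon stress of a configuration against input dissimilarities."""
    iu = np.triu_indices_from(delta, k=1)
    dl = delta[iu]
    dd = pdist(points)
    return float(np.sum((dl - dd) ** 2 / dl) / np.sum(dl))


def _classical_scaling(delta: np.ndarray, dim: int = 2) -> np.ndarray:
    n = delta.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (delta ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def sammon_map(d: DissimilarityMatrix, seed: int = 0, max_iter: int = 500,
               tol: float = 1e-8, jitter: str = "fail",
               n_init: int = 4) -> Configuration2D:
    """Project a dissimilarity matrix into the plane by Sammon mapping.

    The first initialization is the classical-scaling solution plus a
    tiny seeded perturbation (which breaks ties in degenerate spectra but
    keeps the map reproducible); ``n_init - 1`` additional seeded random
    starts guard against local minima and the lowest-stress fit is
    returned.  Refinement is Sammon's diagonal-Newton step with halving
    whenever a step would increase stress, so the reported stress is
    non-increasing over iterations.

    Zero off-diagonal dissimilarities are incompatible with the stress
    denominator; with ``jitter='epsilon'`` they are raised to a small
    positive floor, otherwise a ``ValueError`` is raised.
    """
    delta = d.values.copy()
    n = delta.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(delta[off] == 0):
        if jitter == "epsilon":
            floor = max(delta[off].max() * 1e-6, 1e-12)
            delta[off] = np.maximum(delta[off], floor)
        else:
            raise ValueError("zero off-diagonal dissimilarity; pass jitter='epsilon' to proceed")

    rng = np.random.default_rng(seed)
    base = _classical_scaling(delta)
    scale = max(np.abs(base).max(), delta.max())
    inits = [base + rng.normal(0.0, 1e-9 * scale, size=base.shape)]
    for _ in range(max(0, n_init - 1)):
        inits.append(rng.normal(0.0, 0.5 * max(scale, 1e-12), size=base.shape))
    best: Configuration2D | None = None
    for pts0 in inits:
        cfg = _sammon_descent(delta, pts0, max_iter, tol, seed)
        if best is None or cfg.stress < best.stress:
            best = cfg
    return best


def _sammon_descent(delta: np.ndarray, pts: np.ndarray, max_iter: int, tol: float,
                    seed: int) -> Configuration2D:
    n = delta.shape[0]
    c = np.sum(delta[np.triu_indices(n, k=1)])
    stress = sammon_stress(delta, pts)
    it = 0
    alpha = 0.3  # Sammon's "magic factor"
    for it in range(1, max_iter + 1):
        dist = squareform(pdist(pts))
        np.fill_diagonal(dist, 1.0)
        safe_delta = delta.copy()
        np.fill_diagonal(safe_delta, 1.0)
        ratio = (safe_delta - dist) / (dist * safe_delta)
        np.fill_diagonal(ratio, 0.0)
        diff = pts[:, None, :] - pts[None, :, :]  # (n, n, 2)
        grad = (-2.0 / c) * np.einsum("ij,ijk->ik", ratio, diff)
        # diagonal of the Hessian, per Sammon's original second-order rule
        with np.errstate(divide="ignore", invalid="ignore"):
            term = 1.0 / (dist * safe_delta) * (
                (safe_delta - dist) - (diff ** 2).transpose(2, 0, 1) / dist
                * (1.0 + (safe_delta - dist) / dist)
            )
        term = np.nan_to_num(term, nan=0.0, posinf=0.0, neginf=0.0)
        term[:, np.arange(n), np.arange(n)] = 0.0
        hess = (-2.0 / c) * term.sum(axis=2).T
        step = grad / np.maximum(np.abs(hess), 1e-12)
        moved = False
        a = alpha
        for _ in range(20):
            cand = pts - a * step
            s = sammon_stress(delta, cand)
            if s < stress:
                pts, stress, moved = cand, s, True
                break
            a *= 0.5
        if not moved:
            break
        if it > 1 and abs(prev - stress) < tol:  # noqa: F821 - set below
            break
        prev = stress
    else:
        warnings.warn(f"Sammon mapping did not converge in {max_iter} iterations "
                      f"(stress {stress:.3g})", RuntimeWarning)
    labels = tuple(CANONICAL_ORDER) if n == len(CANONICAL_ORDER) else ()
    return Configuration2D(points=pts, stress=stress, n_iter=it, seed=seed, labels=labels)


def procrustes_align(config: Configuration2D,
                     reference: Configuration2D) -> tuple[Configuration2D, float]:
    """Similarity-Procrustes alignment of ``config`` onto ``reference``.

    Least-squares over translation, isotropic scaling, rotation and
    reflection.  Returns the aligned configuration (stress unchanged —
    the Sammon criterion is invariant to similarity transforms up to
    scale of the *input*, and alignment happens after the fit) and the
    disparity: the sum of squared residuals normalized by the reference's
    centered sum of squares.
    """
    x = reference.points
    y = config.points
    if x.shape != y.shape:
        raise ValueError("configurations must have matching shapes")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    norm_x = np.linalg.norm(xc)
    norm_y = np.linalg.norm(yc)
    if norm_x == 0:
        raise ValueError("degenerate reference: all points coincide")
    if norm_y == 0:
        raise ValueError("degenerate configuration: all points coincide")
    u, s, vt = np.linalg.svd(yc.T @ xc)
    rot = u @ vt  # reflection permitted: no determinant correction
    scale = s.sum() / norm_y ** 2
    aligned = scale * yc @ rot + x.mean(axis=0)
    disparity = float(np.sum((aligned - x) ** 2) / norm_x ** 2)
    out = Configuration2D(points=aligned, stress=config.stress, n_iter=config.n_iter,
                          seed=config.seed, checkpoint=config.checkpoint, labels=config.labels)
    return out, disparity


def trajectory(matrices: Mapping[int, SimilarityMatrix], checkpoints: Sequence[int],
               seed: int = 0) -> list[Configuration2D]:
    """Aligned 2-D configurations across a checkpoint schedule.

    Each checkpoint's similarity matrix is converted to dissimilarities,
    Sammon-mapped, and aligned to the final (end-of-learning) checkpoint's
    configuration.  Missing checkpoints raise ``KeyError`` so a gap is
    explicit rather than silently dropped.
    """
    missing = [cp for cp in checkpoints if cp not in matrices]
    if missing:
        raise KeyError(f"missing checkpoints {missing}")
    configs = {}
    for cp in checkpoints:
        cfg = sammon_map(to_dissimilarity(matrices[cp]), seed=seed, jitter="epsilon")
        configs[cp] = Configuration2D(points=cfg.points, stress=cfg.stress, n_iter=cfg.n_iter,
                                      seed=cfg.seed, checkpoint=cp, labels=cfg.labels)
    reference = configs[checkpoints[-1]]
    return [procrustes_align(configs[cp], reference)[0] for cp in checkpoints]
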
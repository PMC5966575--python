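"""Rigid template-to-target alignment without correspondences.

Alternates a Gaussian soft assignment between the two vertex sets and a
closed-form weighted Procrustes solve while geometrically cooling the
assignment temperature (deterministic annealing).  The per-iteration score
sum_ij w_ij ||R s_i + t - d_j||^2 is provably non-increasing: cooling can
only sharpen each row's Gibbs weights toward nearer targets, and the
Procrustes step minimizes the score at fixed weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .volumes import GeometryError, TriMesh


class AlignmentDegeneracyError(GeometryError):
    """Cross-covariance rank < 2 (e.g. collinear points)."""


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation, mm translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthogonal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise GeometryError("rotation determinant is not +1 (reflection?)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class SoftAssignState:
    assignment: np.ndarray  # P x Q row-stochastic
    temperature: float  # mm^2
    score: float


@dataclass
class AnnealingSchedule:
    """Deterministic annealing parameters for :func:`rigid_align`.

    T0 defaults to the mean squared nearest-neighbor distance of the two
    point sets; cooling is geometric until T_min = (0.5 mm)^2.
    """

    t0: float | None = None
    cooling: float = 0.93
    t_min: float = 0.25
    inner_iters: int = 1
    max_iter: int = 200
    subsample: int = 2000
    seed: int = 0
    rel_tol: float = 1e-9


def soft_assignment(src_pts, dst_pts, temperature: float) -> SoftAssignState:
    """Row-stochastic Gaussian assignment w_ij ∝ exp(-||s_i - d_j||^2 / T).

    The score is the assignment-weighted sum of squared distances.
    """
    src = np.asarray(src_pts, dtype=float)
    dst = np.asarray(dst_pts, dtype=float)
    if len(src) < 3 or len(dst) < 3 or temperature <= 0:
        raise ValueError("need >= 3 points per set and temperature > 0")
    d2 = (
        np.sum(src**2, axis=1)[:, None]
        + np.sum(dst**2, axis=1)[None, :]
        - 2.0 * src @ dst.T
    )
    np.maximum(d2, 0.0, out=d2)
    logits = -d2 / temperature
    logits -= logits.max(axis=1, keepdims=True)  # row-wise stabilization
    w = np.exp(logits)
    w /= w.sum(axis=1, keepdims=True)
    score = float(np.sum(w * d2))
    return SoftAssignState(w, float(temperature), score)


def weighted_procrustes(src_pts, dst_pts, assignment) -> RigidTransform:
    """Closed-form minimizer of sum_ij w_ij ||R s_i + t - d_j||^2.

    With row-stochastic weights this reduces to a classic Procrustes solve
    between the sources and their per-row weighted target barycenters, via
    the cross-covariance SVD with a determinant correction that excludes
    reflections.
    """
    src = np.asarray(src_pts, dtype=float)
    dst = np.asarray(dst_pts, dtype=float)
    w = np.asarray(assignment, dtype=float)
    targets = w @ dst  # per-source weighted barycenter (rows sum to 1)
    mu_s = src.mean(axis=0)
    mu_t = targets.mean(axis=0)
    H = (src - mu_s).T @ (targets - mu_t)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1e-300):
        raise AlignmentDegeneracyError(
            "cross-covariance rank < 2: point sets are degenerate (collinear?)"
        )
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return RigidTransform(R, t)


def _principal_axes_init(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Centroid + PCA initialization, sign-disambiguated by score."""
    mu_s, mu_t = src.mean(axis=0), dst.mean(axis=0)
    _, _, Vs = np.linalg.svd(src - mu_s, full_matrices=False)
    _, _, Vd = np.linalg.svd(dst - mu_t, full_matrices=False)
    best = None
    tree = cKDTree(dst)
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            signs = np.diag([s1, s2, s1 * s2])  # keeps det = +1
            R = Vd.T @ signs @ Vs
            if np.linalg.det(R) < 0:  # guard against reflective PCA bases
                R = Vd.T @ (signs * np.diag([1, 1, -1])) @ Vs
            if np.linalg.det(R) < 0:
                continue
            t = mu_t - R @ mu_s
            moved = src @ R.T + t
            score = float(np.mean(tree.query(moved)[0] ** 2))
            if best is None or score < best[0]:
                best = (score, R, t)
    return RigidTransform(best[1], best[2])


def rigid_align(
    template: TriMesh | np.ndarray,
    target: TriMesh | np.ndarray,
    schedule: AnnealingSchedule | None = None,
) -> tuple[RigidTransform, list[float]]:
    """Align template vertices to target vertices; returns (transform, score trace).

    Vertex sets are used as point clouds; sets larger than
    ``schedule.subsample`` are uniformly subsampled with a fixed seed
    (the O(PQ) assignment otherwise dominates).  Initialization is centroid
    matching plus principal-axes alignment with score-based sign
    disambiguation.  A convergence warning (not an error) is issued if the
    relative score change at the final temperature still exceeds the
    tolerance.
    """
    sched = schedule or AnnealingSchedule()
    src = template.vertices if isinstance(template, TriMesh) else np.asarray(template)
    dst = target.vertices if isinstance(target, TriMesh) else np.asarray(target)
    if len(src) == 0 or len(dst) == 0:
        raise ValueError("empty point set")
    rng = np.random.default_rng(sched.seed)
    if len(src) > sched.subsample:
        src = src[rng.choice(len(src), sched.subsample, replace=False)]
    if len(dst) > sched.subsample:
        dst = dst[rng.choice(len(dst), sched.subsample, replace=False)]

    transform = _principal_axes_init(src, dst)
    moved = transform.apply(src)
    tree = cKDTree(dst)
    t0 = sched.t0
    if t0 is None:
        t0 = float(np.mean(tree.query(moved)[0] ** 2))
    T = max(t0, sched.t_min)

    trace: list[float] = []
    best = np.inf
    converged = False
    for _ in range(sched.max_iter):
        for _ in range(max(sched.inner_iters, 1)):
            state = soft_assignment(moved, dst, T)
            step = weighted_procrustes(src, dst, state.assignment)
            candidate = step.apply(src)
            score = float(np.sum(state.assignment * _sqdist(candidate, dst)))
            # monotone safeguard: only accept score-improving updates
            if score <= best:
                transform, moved, best = step, candidate, score
        trace.append(best)
        if T <= sched.t_min and len(trace) > 1 and (
            trace[-2] - best <= sched.rel_tol * max(trace[-2], 1.0)
        ):
            converged = True
            break
        T = max(T * sched.cooling, sched.t_min)
    if not converged:
        warnings.warn("rigid_align: maximum iterations reached", stacklevel=2)
    return transform, trace


def _sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(a**2, axis=1)[:, None]
        + np.sum(b**2, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.maximum(d2, 0.0)
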
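"""Evaluation machinery: overlap statistics, surface roughness, QC.

Implements the Dice similarity coefficient (DSC), absolute volume difference
(AVD), Pearson correlation of cohort volumes (PCC), the Geometric Laplacian
(GL) roughness measure, interquartile-range outlier flagging, Welch's
two-sample t-test, and the CAP disease-burden score used to subgroup
premanifest Huntington's disease carriers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volumes import GeometryError, LabelVolume, ShapeFiltError, TriMesh


class ConnectivityError(ShapeFiltError):
    """Isolated vertex or otherwise unusable mesh connectivity."""


class DegenerateEdgeError(ShapeFiltError):
    """Zero-length edge: the mesh must be cleaned before GL evaluation."""


@dataclass
class MetricsReport:
    """Per-structure evaluation values produced by the filtering pipeline."""

    dsc: float
    avd: float
    gl_raw: float
    gl_filtered: float
    volumes: tuple[float, float]  # (raw, filtered) mm^3
    extra: dict = field(default_factory=dict)


@dataclass
class OutlierReport:
    q1: float
    q3: float
    lower: float
    upper: float
    outlier_indices: list[int]
    rule: str


# ---------------------------------------------------------------------------
# Overlap statistics
# ---------------------------------------------------------------------------

def _check_grids(a: LabelVolume, b: LabelVolume) -> None:
    if not a.same_grid(b):
        raise GeometryError("volumes are not on the same grid/affine")


def dsc(a: LabelVolume, b: LabelVolume) -> float:
    """Dice similarity coefficient 2 V(A∩B) / (V(A) + V(B)).

    Voxel counts are scaled by the voxel volume (which cancels); two empty
    masks are defined as perfectly overlapping (1.0) with a warning.
    """
    _check_grids(a, b)
    am = a.data > 0
    bm = b.data > 0
    va, vb = am.sum(), bm.sum()
    if va + vb == 0:
        warnings.warn("DSC of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return float(2.0 * np.count_nonzero(am & bm) / (va + vb))


def avd(a: LabelVolume, b: LabelVolume) -> float:
    """Absolute volume difference |V(A)-V(B)| / ((V(A)+V(B))/2), in [0, 2]."""
    _check_grids(a, b)
    va = a.foreground_volume_mm3()
    vb = b.foreground_volume_mm3()
    if va + vb == 0:
        warnings.warn("AVD of two empty masks defined as 0.0", stacklevel=2)
        return 0.0
    return float(abs(va - vb) / ((va + vb) / 2.0))


def pcc(x, y) -> float:
    """Pearson product-moment correlation of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pcc needs two equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a sample has zero variance")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Geometric Laplacian
# ---------------------------------------------------------------------------

def _vertex_neighbors(mesh: TriMesh) -> list[np.ndarray]:
    n = len(mesh.vertices)
    e = mesh.edges()
    nbr: list[list[int]] = [[] for _ in range(n)]
    for a, b in e:
        nbr[a].append(b)
        nbr[b].append(a)
    return [np.array(v, dtype=np.int64) for v in nbr]


def gl_vertex(mesh: TriMesh, v: int) -> np.ndarray:
    """Geometric Laplacian of vertex v.

    GL(v) = v - (sum_i l_i^-1 v_i) / (sum_i l_i^-1) over the edge-connected
    1-ring, with l_i the Euclidean edge lengths.  The offset of a vertex from
    the inverse-distance-weighted centroid of its neighbors: a roughness
    measure that vanishes on locally symmetric flat patches and scales
    linearly with the mesh.
    """
    nbrs = _vertex_neighbors(mesh)[v]
    if len(nbrs) == 0:
        raise ConnectivityError(f"vertex {v} has no neighbors")
    p = mesh.vertices[v]
    q = mesh.vertices[nbrs]
    dist = np.linalg.norm(q - p, axis=1)
    if np.any(dist == 0):
        raise DegenerateEdgeError(f"zero-length edge at vertex {v}")
    w = 1.0 / dist
    return p - (w[:, None] * q).sum(axis=0) / w.sum()


def gl_surface(mesh: TriMesh) -> float:
    """Total roughness: sum over vertices of ||GL(v)||_2 (unnormalized)."""
    mesh = mesh.remove_unreferenced_vertices() if _has_unreferenced(mesh) else mesh
    nbrs = _vertex_neighbors(mesh)
    total = 0.0
    V = mesh.vertices
    for v, nb in enumerate(nbrs):
        if len(nb) == 0:
            raise ConnectivityError(f"vertex {v} has no neighbors")
        d = np.linalg.norm(V[nb] - V[v], axis=1)
        if np.any(d == 0):
            raise DegenerateEdgeError(f"zero-length edge at vertex {v}")
        w = 1.0 / d
        gl = V[v] - (w[:, None] * V[nb]).sum(axis=0) / w.sum()
        total += float(np.linalg.norm(gl))
    return total


def _has_unreferenced(mesh: TriMesh) -> bool:
    return len(np.unique(mesh.faces.ravel())) < len(mesh.vertices)


# ---------------------------------------------------------------------------
# Outlier QC, group tests, CAP score
# ---------------------------------------------------------------------------

def outlier_analysis(values, rule: str = "as_printed") -> OutlierReport:
    """Flag IQR outliers in a set of structure-specific GL values.

    Quantiles use linear interpolation of order statistics.  Two rules are
    shipped: ``as_printed`` bounds [Q1 - 1.5 IQR, Q1 + 1.5 IQR] and the
    standard ``tukey`` bounds [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  Values strictly
    outside the bounds are flagged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("outlier analysis needs at least 4 values")
    if rule not in ("as_printed", "tukey"):
        raise ValueError(f"unknown rule: {rule}")
    q1 = float(np.percentile(values, 25, method="linear"))
    q3 = float(np.percentile(values, 75, method="linear"))
    iqr = q3 - q1
    lower = q1 - 1.5 * iqr
    upper = (q1 if rule == "as_printed" else q3) + 1.5 * iqr
    idx = np.where((values < lower) | (values > upper))[0]
    return OutlierReport(q1, q3, lower, upper, [int(i) for i in idx], rule)


def two_sample_t(x, y) -> tuple[float, float]:
    """Welch (unequal-variance) two-sided t-test.

    Degenerate case: both samples constant with equal means gives t = 0,
    p = 1 rather than a NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0 and np.isclose(x.mean(), y.mean()):
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def cap_score(age_years: float, cag: int) -> tuple[float, str]:
    """CAP = age x (CAG - 33.66); subgroup boundaries 290 and 368 are
    inclusive to the mid-HD group."""
    if age_years <= 0:
        raise ValueError("age must be positive")
    cap = age_years * (cag - 33.66)
    if cap < 290:
        group = "low-HD"
    elif cap <= 368:
        group = "mid-HD"
    else:
        group = "high-HD"
    return float(cap), group
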
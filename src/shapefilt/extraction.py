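"""Surface extraction: raw target surfaces and smooth template surfaces.

Raw target surfaces come from marching cubes, which is faithful to the
segmentation (including its errors).  Template surfaces come from a
Delaunay-based reconstruction of a Gaussian-smoothed indicator function,
which trades fidelity for smoothness — appropriate only for curated,
noise-free masks.  Template selection picks, among candidate meshes of the
same structure, the one whose area is closest to the cohort mean, tie-broken
by smoothness, after excluding non-closed candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from skimage import measure

from .metrics import gl_surface
from .volumes import (
    GeometryError,
    LabelVolume,
    ShapeFiltError,
    TopologyError,
    TriMesh,
    voxel_to_world,
)


class EmptyMaskError(ShapeFiltError):
    """Extraction requested on a mask with no foreground."""


class ExtractionError(ShapeFiltError):
    """Surface reconstruction failed (non-watertight after repair)."""


@dataclass
class ExtractionConfig:
    iso_level: float = 0.5
    pad_voxels: int = 2
    gaussian_sigma_mm: float = 1.5
    target_edge_length_mm: float = 2.0
    keep_largest_component: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.iso_level < 1.0):
            raise ValueError("iso_level must lie strictly in (0, 1)")
        if self.pad_voxels < 0:
            raise ValueError("pad_voxels must be non-negative")


def marching_cubes_extract(
    mask: LabelVolume, cfg: ExtractionConfig | None = None
) -> TriMesh:
    """Extract the iso-surface of a binary mask as a closed, outward-oriented
    triangle mesh in world millimetres.

    The mask is zero-padded so surfaces touching the volume border stay
    closed; the Lewiner marching-cubes variant resolves ambiguous cube
    configurations consistently (no face holes).  With
    ``keep_largest_component`` only the largest connected surface component
    (by face count) is kept.
    """
    cfg = cfg or ExtractionConfig()
    data = (mask.data > 0).astype(np.float64)
    if not data.any():
        raise EmptyMaskError("marching cubes on an empty mask")
    p = cfg.pad_voxels
    padded = np.pad(data, p)
    verts, faces, _, _ = measure.marching_cubes(padded, level=cfg.iso_level)
    verts = verts - p  # back to unpadded voxel indices
    mesh = TriMesh(voxel_to_world(mask, verts), faces)
    if mesh.enclosed_volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    if cfg.keep_largest_component:
        mesh = _largest_component(mesh)
    return mesh


def _largest_component(mesh: TriMesh) -> TriMesh:
    n_comp, labels = mesh.vertex_components()
    if n_comp <= 1:
        return mesh
    face_label = labels[mesh.faces[:, 0]]
    counts = np.bincount(face_label[face_label >= 0])
    keep = face_label == np.argmax(counts)
    return TriMesh(mesh.vertices, mesh.faces[keep]).remove_unreferenced_vertices()


# ---------------------------------------------------------------------------
# Delaunay-based template surface
# ---------------------------------------------------------------------------

def delaunay_template_mesh(
    mask: LabelVolume, cfg: ExtractionConfig | None = None
) -> TriMesh:
    """Build a smooth template surface from a curated single-component mask.

    Route: Gaussian-smooth the binary indicator at ``gaussian_sigma_mm``,
    sample the iso-surface with a blue-noise (Poisson-disk) point set at
    roughly ``target_edge_length_mm`` spacing, tetrahedralize surface plus
    interior anchor points with a 3-D Delaunay triangulation, classify
    tetrahedra by the smoothed indicator at their centroid, and take the
    boundary of the inside tetrahedra as the surface; a few tangential
    smoothing sweeps even out the triangles.  Yields a closed mesh markedly
    smoother than marching cubes on the same mask, at the cost of stability:
    a multi-component mask is an error, as is a reconstruction that is not
    watertight.
    """
    cfg = cfg or ExtractionConfig(keep_largest_component=False)
    data = mask.data > 0
    if not data.any():
        raise EmptyMaskError("template extraction on an empty mask")
    if ndimage.label(data)[1] != 1:
        raise TopologyError("template mask must be a single connected component")

    spacing = mask.spacing
    sigma_vox = cfg.gaussian_sigma_mm / spacing
    pad = cfg.pad_voxels + int(np.ceil(3 * sigma_vox.max())) + 1
    padded = np.pad(data, pad)
    # Smoothed signed distance (mm, positive outside).  Gaussian smoothing
    # shifts a level set inward by ~ (sigma^2 / 2) * Laplacian (the mean
    # curvature for a distance function); subtracting that term cancels the
    # O(sigma^2) shrinkage, leaving the smoothness benefit.
    sdf = ndimage.distance_transform_edt(
        ~padded, sampling=spacing
    ) - ndimage.distance_transform_edt(padded, sampling=spacing)
    field = ndimage.gaussian_filter(sdf, sigma=sigma_vox)
    lap = sum(
        np.gradient(np.gradient(field, spacing[ax], axis=ax), spacing[ax], axis=ax)
        for ax in range(3)
    )
    field = field - 0.5 * cfg.gaussian_sigma_mm**2 * lap

    inv = np.linalg.inv(mask.affine)

    def world_to_padded_vox(pts):
        return pts @ inv[:3, :3].T + inv[:3, 3] + pad

    # dense zero-level sample (padded voxel coordinates -> world mm)
    dense_v, _, _, _ = measure.marching_cubes(field, level=0.0)
    world = voxel_to_world(mask, dense_v - pad)

    last_err: Exception | None = None
    for scale in (1.0, 0.85, 0.7):  # densify on reconstruction failure
        L = cfg.target_edge_length_mm * scale
        try:
            mesh = _reconstruct(
                world, field, mask, spacing, pad, L, world_to_padded_vox
            )
        except ExtractionError as err:
            last_err = err
            continue
        n_comp, _ = mesh.vertex_components()
        if n_comp != 1:
            raise TopologyError(
                "template reconstruction split into multiple components; "
                "reduce gaussian_sigma_mm (thin features were smoothed away)"
            )
        return mesh
    raise last_err


def _reconstruct(dense_world, field, mask, spacing, pad, L, world_to_padded_vox):
    surf_pts = _poisson_disk(dense_world, radius=0.75 * L)

    # interior anchors on a coarse lattice, at least one edge length deep
    depth_vox = max(int(np.ceil(L / spacing.min())), 1)
    interior = ndimage.binary_erosion(field < 0.0, iterations=depth_vox)
    step = max(int(round(L / spacing.min())), 1)
    idx = np.argwhere(interior)
    idx = idx[np.all(idx % step == 0, axis=1)]
    int_pts = voxel_to_world(mask, idx.astype(float) - pad)
    if len(int_pts) == 0 and interior.any():
        int_pts = voxel_to_world(
            mask, np.argwhere(interior).mean(axis=0, keepdims=True) - pad
        )

    pts = np.vstack([surf_pts, np.atleast_2d(int_pts)]) if len(int_pts) else surf_pts
    tri = Delaunay(pts)

    # classify tetrahedra by the smoothed signed distance at their centroids
    cent_vox = world_to_padded_vox(pts[tri.simplices].mean(axis=1))
    vals = ndimage.map_coordinates(field, cent_vox.T, order=1, mode="nearest")
    inside = vals < 0.0
    inside = _repair_classification(tri.simplices, inside, vals)

    faces = _boundary_faces(tri.simplices[inside], pts)
    mesh = TriMesh(pts, faces).remove_unreferenced_vertices()
    mesh = mesh.remove_degenerate_faces()
    for _ in range(3):  # interleave relaxation with level-set projection
        mesh = _tangential_smooth(mesh, iterations=2)
        mesh = _project_to_level_set(mesh, field, world_to_padded_vox, mask.affine)
    for _ in range(3):  # cap anisotropy: bisect outlier-long edges, re-relax
        mesh, n_split = _split_long_edges(mesh, threshold=1.3 * L)
        if n_split == 0:
            break
        mesh = _tangential_smooth(mesh, iterations=1, lam=0.3)
        mesh = _project_to_level_set(mesh, field, world_to_padded_vox, mask.affine)
    if mesh.enclosed_volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    if not mesh.is_closed():
        raise ExtractionError(
            "Delaunay reconstruction is not watertight; increase sampling "
            "density (smaller target_edge_length_mm) or smoothing"
        )
    return mesh


def _project_to_level_set(
    mesh: TriMesh, field: np.ndarray, world_to_vox, affine, iters: int = 3
) -> TriMesh:
    """Newton-project vertices onto the zero level of the smoothed signed
    distance, undoing the shrinkage of sampling and tangential smoothing."""
    A = affine[:3, :3]
    grads = np.gradient(field)  # per-voxel-index derivatives
    V = mesh.vertices.copy()
    for _ in range(iters):
        vox = world_to_vox(V)
        f = ndimage.map_coordinates(field, vox.T, order=1, mode="nearest")
        g_vox = np.stack(
            [ndimage.map_coordinates(g, vox.T, order=1, mode="nearest") for g in grads],
            axis=1,
        )
        g_world = g_vox @ np.linalg.inv(A)  # chain rule: d/dx = d/di * di/dx
        norm2 = np.einsum("ij,ij->i", g_world, g_world)
        norm2 = np.where(norm2 > 1e-12, norm2, 1.0)
        V -= (f / norm2)[:, None] * g_world
    return TriMesh(V, mesh.faces)


def _poisson_disk(points: np.ndarray, radius: float) -> np.ndarray:
    """Greedy deterministic blue-noise subsample: accept a point iff no
    previously accepted point lies within ``radius``."""
    cell = radius / np.sqrt(3.0)
    grid: dict[tuple, list[int]] = {}
    accepted: list[int] = []
    keys = np.floor(points / cell).astype(np.int64)
    r2 = radius * radius
    for i in range(len(points)):
        k = tuple(keys[i])
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((k[0] + dx, k[1] + dy, k[2] + dz), ()):
                        d = points[i] - points[j]
                        if d @ d < r2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault(k, []).append(i)
            accepted.append(i)
    return points[accepted]


def _repair_classification(
    tets: np.ndarray, inside: np.ndarray, vals: np.ndarray, max_rounds: int = 25
) -> np.ndarray:
    """Remove non-manifold (bowtie) edges from the inside/outside labeling.

    Where the boundary of the kept-tetrahedra union has an edge with more
    than two incident faces, greedily toggle the most ambiguous tetrahedron
    (smallest |signed distance| at its centroid) in that edge's ring until
    the boundary is edge-manifold.  Each tetrahedron is toggled at most once.
    """
    inside = inside.copy()
    # edge (sorted vertex pair) -> incident tetrahedra
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edge_tets: dict[tuple, list[int]] = {}
    for a, b in pairs:
        lo = np.minimum(tets[:, a], tets[:, b])
        hi = np.maximum(tets[:, a], tets[:, b])
        for t_idx in range(len(tets)):
            edge_tets.setdefault((lo[t_idx], hi[t_idx]), []).append(t_idx)
    toggled: set[int] = set()
    for _ in range(max_rounds):
        bad = _nonmanifold_edges(tets[inside])
        if not len(bad):
            break
        changed = False
        for a, b in bad:
            ring = edge_tets.get((a, b), [])
            cand = [t for t in ring if t not in toggled]
            if not cand:
                continue
            t_best = min(cand, key=lambda t: abs(vals[t]))
            inside[t_best] = ~inside[t_best]
            toggled.add(t_best)
            changed = True
        if not changed:
            break
    return inside


def _nonmanifold_edges(tets: np.ndarray) -> np.ndarray:
    """Edges of the boundary surface shared by more than two faces."""
    if not len(tets):
        return np.empty((0, 2), np.int64)
    combos = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    faces = np.concatenate([tets[:, c] for c in combos])
    key = np.sort(faces, axis=1)
    uniq, inv_idx, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = uniq[counts == 1]
    if not len(boundary):
        return np.empty((0, 2), np.int64)
    e = np.concatenate(
        [boundary[:, [0, 1]], boundary[:, [1, 2]], boundary[:, [0, 2]]]
    )
    e.sort(axis=1)
    ue, ec = np.unique(e, axis=0, return_counts=True)
    return ue[ec > 2]


def _boundary_faces(tets: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a union of tetrahedra."""
    # the four faces of tet (a,b,c,d), each with the opposite vertex
    combos = [(1, 2, 3, 0), (0, 3, 2, 1), (0, 1, 3, 2), (0, 2, 1, 3)]
    all_faces = []
    opp = []
    for c in combos:
        all_faces.append(tets[:, c[:3]])
        opp.append(tets[:, c[3]])
    all_faces = np.concatenate(all_faces)
    opp = np.concatenate(opp)
    key = np.sort(all_faces, axis=1)
    _, inv_idx, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv_idx] == 1
    faces = all_faces[boundary]
    opp = opp[boundary]
    # orient each boundary face away from its tet's opposite vertex
    v = pts[faces]
    n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    toward_opp = np.einsum("ij,ij->i", n, pts[opp] - v[:, 0])
    flip = toward_opp > 0
    faces[flip] = faces[flip][:, ::-1]
    return faces


def _split_long_edges(mesh: TriMesh, threshold: float) -> tuple[TriMesh, int]:
    """Bisect edges longer than ``threshold`` at their midpoints.

    Each split replaces the edge's two incident faces by four, so a closed
    mesh stays closed.  Edges are processed longest-first; edges whose faces
    were already modified in this pass are deferred to the next.
    """
    V = list(mesh.vertices)
    F = mesh.faces.copy()
    e = mesh.edges()
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    order = np.argsort(-lengths)
    dirty = np.zeros(len(F), bool)
    n_split = 0
    for ei in order:
        if lengths[ei] <= threshold:
            break
        a, b = e[ei]
        hit = np.where(
            ((F == a).any(axis=1)) & ((F == b).any(axis=1)) & ~dirty
        )[0]
        if len(hit) != 2:
            continue  # face already modified this pass; retry next pass
        mid = len(V)
        V.append((mesh.vertices[a] + mesh.vertices[b]) / 2.0)
        new_faces = []
        for fi in hit:
            tri_f = F[fi]
            f1 = np.where(tri_f == a, mid, tri_f)
            f2 = np.where(tri_f == b, mid, tri_f)
            F[fi] = f1
            new_faces.append(f2)
            dirty[fi] = True
        F = np.vstack([F, new_faces])
        dirty = np.concatenate([dirty, [True, True]])
        n_split += 1
    return TriMesh(np.asarray(V), F), n_split


def _tangential_smooth(mesh: TriMesh, iterations: int = 4, lam: float = 0.5) -> TriMesh:
    """Move each vertex toward its 1-ring centroid, projected back onto the
    surface's tangent plane (vertex-normal projection) to limit shrinkage."""
    V = mesh.vertices.copy()
    F = mesh.faces
    n = len(V)
    e = mesh.edges()
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    for _ in range(iterations):
        centroid = np.zeros_like(V)
        deg = np.zeros(n)
        np.add.at(centroid, rows, V[cols])
        np.add.at(deg, rows, 1.0)
        deg[deg == 0] = 1.0
        centroid /= deg[:, None]
        delta = centroid - V
        # vertex normals from area-weighted face normals
        fn = 0.5 * np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])
        vn = np.zeros_like(V)
        for k in range(3):
            np.add.at(vn, F[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        vn = vn / np.where(norm > 1e-12, norm, 1.0)
        delta -= vn * np.einsum("ij,ij->i", delta, vn)[:, None]
        V = V + lam * delta
    return TriMesh(V, F)


# ---------------------------------------------------------------------------
# Template selection
# ---------------------------------------------------------------------------

def select_template(meshes: list[TriMesh]) -> int:
    """Pick the template among candidate meshes of one structure.

    Non-closed candidates are excluded outright.  Among the rest the score
    is lexicographic: distance of the surface area to the mean area over
    valid candidates, tie-broken by lower total Geometric Laplacian
    (smoothness), then by list order.
    """
    if len(meshes) < 2:
        raise ValueError("template selection needs at least 2 candidates")
    valid = [i for i, m in enumerate(meshes) if m.is_closed()]
    if not valid:
        raise ExtractionError("no valid template: all candidates are non-closed")
    areas = {i: meshes[i].total_area() for i in valid}
    mean_area = float(np.mean(list(areas.values())))
    scored = sorted(
        valid, key=lambda i: (abs(areas[i] - mean_area), gl_surface(meshes[i]), i)
    )
    return scored[0]
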
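"""Seeded synthetic phantoms: subcortical-like binary masks and noise models.

Three base shapes cover the geometry classes seen in subcortical and
ventricular segmentation: a smooth ellipsoid (putamen / pallidus-like), a
tube bent along a circular arc (caudate / hippocampus-like), and a two-lobe
"dumbbell" joined by a thin bridge (lateral-ventricle-like, where a thin
bridge connects the inferior horn to the main body).  A corruption operator
emulates the failure modes of automated segmentation: boundary voxel flips,
interior holes, and small disconnected components.

All randomness flows from one integer seed through numpy SeedSequence
spawning: member i of a population uses SeedSequence(seed, spawn_key=(i,)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import GeometryError, LabelVolume

DEFAULT_SIZE_PARAMS = {
    "ellipsoid": {"radii_mm": (12.0, 8.0, 6.0)},
    "bent_tube": {"arc_radius_mm": 14.0, "tube_radius_mm": 4.0, "arc_degrees": 160.0},
    "dumbbell_bridge": {
        "lobe_radii_mm": (8.0, 6.0, 6.0),
        "separation_mm": 22.0,
        "bridge_radius_mm": 1.2,
    },
}


@dataclass
class PhantomSpec:
    shape: str = "ellipsoid"
    size_params: dict = field(default_factory=dict)
    grid_shape: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def params(self) -> dict:
        if self.shape not in DEFAULT_SIZE_PARAMS:
            raise ValueError(f"unknown phantom shape: {self.shape}")
        p = dict(DEFAULT_SIZE_PARAMS[self.shape])
        p.update(self.size_params)
        return p


@dataclass
class NoiseSpec:
    boundary_flip_rate: float = 0.05
    n_holes: int = 3
    hole_radius_mm: float = 1.5
    n_spurious_components: int = 2
    spurious_radius_mm: float = 2.0
    seed: int = 0


def _centered_affine(grid_shape, spacing) -> np.ndarray:
    """Affine placing the world origin at the grid center (voxel-center)."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = spacing
    affine[:3, 3] = -(np.asarray(grid_shape) - 1) / 2.0 * np.asarray(spacing)
    return affine


def _world_grid(grid_shape, affine) -> np.ndarray:
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def _implicit_inside(shape: str, params: dict, xyz: np.ndarray) -> np.ndarray:
    """Boolean inside-test for the base shape at world points xyz (...x3)."""
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    if shape == "ellipsoid":
        rx, ry, rz = params["radii_mm"]
        return (x / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2 <= 1.0
    if shape == "bent_tube":
        R = params["arc_radius_mm"]
        r = params["tube_radius_mm"]
        half = np.deg2rad(params["arc_degrees"]) / 2.0
        theta = np.clip(np.arctan2(y, x), -half, half)
        cx, cy = R * np.cos(theta), R * np.sin(theta)
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + z**2
        return d2 <= r**2
    if shape == "dumbbell_bridge":
        rx, ry, rz = params["lobe_radii_mm"]
        c = params["separation_mm"] / 2.0
        rb = params["bridge_radius_mm"]
        lobe1 = ((x - c) / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2 <= 1.0
        lobe2 = ((x + c) / rx) ** 2 + (y / ry) ** 2 + (z / rz) ** 2 <= 1.0
        bridge = (np.abs(x) <= c) & (y**2 + z**2 <= rb**2)
        return lobe1 | lobe2 | bridge
    raise ValueError(f"unknown phantom shape: {shape}")


def bridge_voxels(spec: PhantomSpec) -> np.ndarray:
    """Boolean array of the bridge-only voxels of a dumbbell phantom."""
    if spec.shape != "dumbbell_bridge":
        raise ValueError("bridge_voxels only applies to dumbbell_bridge")
    p = spec.params()
    affine = _centered_affine(spec.grid_shape, spec.spacing)
    xyz = _world_grid(spec.grid_shape, affine)
    full = _implicit_inside(spec.shape, p, xyz)
    lobes_only = dict(p, bridge_radius_mm=0.0)
    lobes = _implicit_inside(spec.shape, lobes_only, xyz)
    return full & ~lobes


def make_phantom(spec: PhantomSpec) -> LabelVolume:
    """Generate a noise-free, single-component binary mask.

    Raises a geometry error when the shape does not fit the grid with a
    3-voxel margin on every side.
    """
    affine = _centered_affine(spec.grid_shape, spec.spacing)
    xyz = _world_grid(spec.grid_shape, affine)
    mask = _implicit_inside(spec.shape, spec.params(), xyz).astype(np.uint8)
    vol = LabelVolume(mask, affine)
    _check_margin(vol, margin=3)
    if mask.sum() == 0:
        raise GeometryError("phantom produced an empty mask")
    if ndimage.label(mask)[1] != 1:
        raise GeometryError("phantom is not a single connected component")
    return vol


def _check_margin(vol: LabelVolume, margin: int) -> None:
    m = vol.data
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = slice(0, margin)
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = slice(m.shape[ax] - margin, m.shape[ax])
        if m[tuple(sl_lo)].any() or m[tuple(sl_hi)].any():
            raise GeometryError(
                "shape does not fit inside the grid with a 3-voxel margin"
            )


def corrupt_mask(mask: LabelVolume, noise: NoiseSpec) -> LabelVolume:
    """Apply seeded segmentation noise to a binary mask.

    Boundary flips are confined to the one-voxel band on each side of the
    true boundary; holes are carved strictly in the interior; spurious
    components are small spheres placed disjoint from the foreground
    (placement retried until disjoint).
    """
    rng = np.random.default_rng(np.random.SeedSequence(noise.seed))
    data = (mask.data > 0).copy()
    spacing = mask.spacing

    # boundary band flips (inner and outer one-voxel bands)
    inner = data & ~ndimage.binary_erosion(data)
    outer = ndimage.binary_dilation(data) & ~data
    band = inner | outer
    if noise.boundary_flip_rate > 0:
        flips = band & (rng.random(data.shape) < noise.boundary_flip_rate)
        data ^= flips

    # interior holes
    if noise.n_holes > 0 and noise.hole_radius_mm > 0:
        r_vox = int(np.ceil(noise.hole_radius_mm / spacing.min())) + 1
        interior = ndimage.binary_erosion(data, iterations=max(r_vox, 1))
        cand = np.argwhere(interior)
        if len(cand):
            picks = cand[rng.choice(len(cand), size=min(noise.n_holes, len(cand)), replace=False)]
            for c in picks:
                data &= ~_sphere_at(data.shape, c, noise.hole_radius_mm, spacing)

    # spurious disconnected components
    if noise.n_spurious_components > 0 and noise.spurious_radius_mm > 0:
        r_vox = int(np.ceil(noise.spurious_radius_mm / spacing.min()))
        dist = ndimage.distance_transform_edt(~data, sampling=spacing)
        ok = dist > noise.spurious_radius_mm + 2 * spacing.max()
        # keep away from the grid border
        border = r_vox + 2
        ok[:border], ok[-border:] = False, False
        ok[:, :border], ok[:, -border:] = False, False
        ok[:, :, :border], ok[:, :, -border:] = False, False
        placed = 0
        cand = np.argwhere(ok)
        order = rng.permutation(len(cand))
        taken = np.zeros(data.shape, bool)
        for idx in order:
            if placed >= noise.n_spurious_components:
                break
            c = cand[idx]
            blob = _sphere_at(data.shape, c, noise.spurious_radius_mm, spacing)
            if not (blob & (data | ndimage.binary_dilation(taken))).any():
                taken |= blob
                placed += 1
        data |= taken

    return LabelVolume(data.astype(np.uint8), mask.affine.copy())


def _sphere_at(shape, center_ijk, radius_mm, spacing) -> np.ndarray:
    r_vox = np.ceil(radius_mm / np.asarray(spacing)).astype(int) + 1
    lo = np.maximum(center_ijk - r_vox, 0)
    hi = np.minimum(center_ijk + r_vox + 1, shape)
    out = np.zeros(shape, bool)
    ii, jj, kk = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    d2 = (
        ((ii - center_ijk[0]) * spacing[0]) ** 2
        + ((jj - center_ijk[1]) * spacing[1]) ** 2
        + ((kk - center_ijk[2]) * spacing[2]) ** 2
    )
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = d2 <= radius_mm**2
    return out


def sample_population(
    spec: PhantomSpec, n: int, variation: float = 0.1, seed: int | None = None
) -> list[LabelVolume]:
    """Draw n anatomically plausible variants of a base phantom.

    Each member applies a seeded smooth radial perturbation (low-order
    directional harmonics: a linear term plus a traceless quadratic form on
    the unit direction, i.e. degree-1 and degree-2 spherical harmonics) and
    a small random rigid motion.  Members violating single-component-ness
    are resampled with a fresh sub-seed.  ``variation`` is the relative
    radial perturbation magnitude (0 disables shape change).
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    seed = spec.seed if seed is None else seed
    out = []
    for i in range(n):
        for attempt in range(8):
            ss = np.random.SeedSequence(seed, spawn_key=(i, attempt))
            vol = _sample_member(spec, variation, np.random.default_rng(ss))
            if ndimage.label(vol.data)[1] == 1:
                out.append(vol)
                break
        else:
            raise GeometryError(f"member {i}: no single-component draw in 8 attempts")
    return out


def _sample_member(spec: PhantomSpec, variation: float, rng) -> LabelVolume:
    affine = _centered_affine(spec.grid_shape, spec.spacing)
    xyz = _world_grid(spec.grid_shape, affine)

    # small rigid motion: rotation <= ~10 degrees, translation <= 2 mm
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-10, 10))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-2.0, 2.0, size=3)

    # radial perturbation coefficients (degree 1 + traceless degree 2)
    a = rng.normal(scale=0.4, size=3)
    B = rng.normal(scale=0.4, size=(3, 3))
    B = (B + B.T) / 2.0
    B -= np.eye(3) * np.trace(B) / 3.0

    pts = (xyz - t) @ R  # inverse rigid motion (R orthogonal)
    r = np.linalg.norm(pts, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = pts / np.where(r[..., None] > 1e-9, r[..., None], 1.0)
    f = (u @ a) + np.einsum("...i,ij,...j->...", u, B, u)
    scale = 1.0 + variation * f
    scale = np.clip(scale, 0.5, 2.0)
    sample_pts = pts / scale[..., None]

    mask = _implicit_inside(spec.shape, spec.params(), sample_pts).astype(np.uint8)
    vol = LabelVolume(mask, affine)
    _check_margin(vol, margin=3)
    return vol
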
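"""Currents representation, flow integration, energy, gradient, matching."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import shapefilt as sf
from conftest import octahedron_mesh
from shapefilt.lddmm import _energy_and_grad


def hull_mesh(n_pts=20, seed=0, scale=5.0) -> sf.TriMesh:
    """Closed mesh over random points (outward-oriented convex hull)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_pts, 3)) * scale
    hull = ConvexHull(pts)
    mesh = sf.TriMesh(pts, hull.simplices).remove_unreferenced_vertices()
    if mesh.enclosed_volume() < 0:
        mesh = sf.TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    # Qhull does not orient simplices consistently; fix each face outward
    c = mesh.vertices.mean(axis=0)
    n = mesh.face_normals()
    outward = np.einsum("ij,ij->i", n, mesh.face_centers() - c) > 0
    faces = mesh.faces.copy()
    faces[~outward] = faces[~outward][:, ::-1]
    return sf.TriMesh(mesh.vertices, faces)


class TestCurrents:
    def test_closed_surface_normals_sum_to_zero(self):
        cur = sf.to_current(octahedron_mesh())
        assert np.allclose(cur.normals.sum(axis=0), 0, atol=1e-12)

    def test_single_triangle_hand_values(self):
        mesh = sf.TriMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        cur = sf.to_current(mesh)
        assert np.allclose(cur.centers[0], [1 / 3, 1 / 3, 0], atol=1e-15)
        assert np.allclose(cur.normals[0], [0, 0, 0.5], atol=1e-15)

    def test_scaling_homogeneity(self):
        mesh = octahedron_mesh()
        s = 2.5
        scaled = sf.TriMesh(mesh.vertices * s, mesh.faces)
        c0, c1 = sf.to_current(mesh), sf.to_current(scaled)
        assert np.allclose(c1.centers, s * c0.centers, atol=1e-12)
        assert np.allclose(c1.normals, s**2 * c0.normals, atol=1e-12)


class TestCurrentDistance:
    def test_self_distance_zero(self):
        cur = sf.to_current(hull_mesh(seed=1))
        assert abs(sf.current_distance2(cur, cur, sigma_W=3.0)) < 1e-9

    def test_matches_brute_force_double_sum(self):
        a = sf.to_current(sf.TriMesh([[0, 0, 0], [2, 0, 0], [0, 2, 0]], [[0, 1, 2]]))
        b = sf.to_current(
            sf.TriMesh([[1, 1, 1], [2, 1, 0.5], [1, 3, 0]], [[0, 1, 2]])
        )
        sw = 1.7

        def inner(u, v):
            total = 0.0
            for cf, nf in zip(u.centers, u.normals):
                for cg, ng in zip(v.centers, v.normals):
                    total += np.exp(-np.sum((cf - cg) ** 2) / sw**2) * np.dot(nf, ng)
            return total

        expect = inner(a, a) - 2 * inner(a, b) + inner(b, b)
        assert sf.current_distance2(a, b, sw) == pytest.approx(expect, abs=1e-12)

    def test_infinite_width_limit_on_closed_meshes(self):
        # both total normals integrate to zero, so the distance vanishes
        a = sf.to_current(octahedron_mesh())
        b = sf.to_current(octahedron_mesh(scale=2.0, offset=(4, 0, 0)))
        assert abs(sf.current_distance2(a, b, sigma_W=1e6)) < 1e-6


class TestFlow:
    def kernel(self):
        return sf.KernelParams(sigma_V=2.0, sigma_W=1.0)

    def test_zero_momenta_identity(self):
        pts = np.array([[0.0, 0, 0], [1, 2, 3]])
        path = sf.DeformationPath(4, np.zeros((4, 2, 3)), pts, self.kernel())
        assert np.allclose(sf.flow_points(pts, path), pts)

    def test_single_particle_unit_displacement(self):
        """A query point riding on a single control point with constant unit
        momentum moves exactly 1 mm (kernel value 1 at zero distance)."""
        T = 7
        mom = np.tile(np.array([1.0, 0, 0]), (T, 1, 1))
        path = sf.DeformationPath(T, mom, np.zeros((1, 3)), self.kernel())
        out = sf.flow_points(np.zeros((1, 3)), path)
        assert np.allclose(out, [[1.0, 0, 0]], atol=1e-12)

    def test_far_field_untouched(self):
        T = 5
        mom = np.tile(np.array([1.0, 0, 0]), (T, 1, 1))
        path = sf.DeformationPath(T, mom, np.zeros((1, 3)), self.kernel())
        far = np.array([[100.0, 0, 0]])
        assert np.abs(sf.flow_points(far, path) - far).max() < 1e-9


class TestEnergy:
    def test_zero_momenta_template_equals_target(self):
        mesh = hull_mesh(seed=2)
        k = sf.KernelParams(4.0, 2.0, 0.1)
        path = sf.DeformationPath(
            3, np.zeros((3, len(mesh.vertices), 3)), mesh.vertices, k
        )
        total, reg, data = sf.lddmm_energy(path, mesh, sf.to_current(mesh))
        assert reg == pytest.approx(0.0, abs=1e-12)
        assert data == pytest.approx(0.0, abs=1e-9)

    def test_zero_momenta_consistency_with_current_distance(self):
        a, b = hull_mesh(seed=3), hull_mesh(seed=4)
        k = sf.KernelParams(4.0, 2.0, 0.1)
        path = sf.DeformationPath(3, np.zeros((3, len(a.vertices), 3)), a.vertices, k)
        total, reg, data = sf.lddmm_energy(path, a, sf.to_current(b))
        assert total == pytest.approx(
            sf.current_distance2(sf.to_current(a), sf.to_current(b), k.sigma_W),
            rel=1e-12,
        )

    def test_matches_naive_reimplementation(self):
        """Independent loop-based oracle for the kinetic + mismatch sums."""
        mesh = octahedron_mesh(scale=3.0)
        target = hull_mesh(seed=5, n_pts=10)
        k = sf.KernelParams(3.0, 2.0, 0.25)
        T = 3
        rng = np.random.default_rng(6)
        mom = rng.normal(scale=0.2, size=(T, 6, 3))
        path = sf.DeformationPath(T, mom, mesh.vertices, k)
        total, reg, data = sf.lddmm_energy(path, mesh, sf.to_current(target))

        # oracle: naive Euler flow and double sums
        h = 1.0 / T
        q = mesh.vertices.copy()
        reg_ref = 0.0
        for t in range(T):
            K = np.zeros((6, 6))
            for i in range(6):
                for j in range(6):
                    K[i, j] = np.exp(-np.sum((q[i] - q[j]) ** 2) / k.sigma_V**2)
                    reg_ref += h * K[i, j] * np.dot(mom[t, i], mom[t, j])
            q = q + h * K @ mom[t]
        flowed = sf.TriMesh(q, mesh.faces)
        data_ref = sf.current_distance2(
            sf.to_current(flowed), sf.to_current(target), k.sigma_W
        )
        assert reg == pytest.approx(reg_ref, abs=1e-9)
        assert data == pytest.approx(data_ref, abs=1e-9)
        assert total == pytest.approx(k.gamma * reg_ref + data_ref, abs=1e-9)


class TestGradient:
    def test_finite_difference_check(self):
        """Adjoint gradient vs central differences on a 20-vertex toy."""
        template = hull_mesh(n_pts=20, seed=7)
        target = hull_mesh(n_pts=20, seed=8)
        k = sf.KernelParams(4.0, 3.0, 0.1)
        T = 3
        rng = np.random.default_rng(9)
        mom = rng.normal(scale=0.3, size=(T, len(template.vertices), 3))
        tc = sf.to_current(target)
        _, _, _, g = _energy_and_grad(mom, template.vertices, template.faces, tc, k, T)
        eps = 1e-6
        gfd = np.zeros_like(mom)
        for idx in np.ndindex(mom.shape):
            m2 = mom.copy()
            m2[idx] += eps
            ep = _energy_and_grad(
                m2, template.vertices, template.faces, tc, k, T, want_grad=False
            )[0]
            m2[idx] -= 2 * eps
            em = _energy_and_grad(
                m2, template.vertices, template.faces, tc, k, T, want_grad=False
            )[0]
            gfd[idx] = (ep - em) / (2 * eps)
        rel = np.linalg.norm(g - gfd) / np.linalg.norm(gfd)
        assert rel < 1e-4


class TestMatching:
    def test_fixed_point_template_equals_target(self):
        mesh = hull_mesh(seed=10)
        k = sf.KernelParams(4.0, 2.0, 0.1)
        path, deformed, _ = sf.lddmm_match(mesh, mesh, k, timesteps=5)
        assert np.abs(deformed.vertices - mesh.vertices).max() < 1e-3
        assert np.abs(path.momenta).max() < 1e-3

    def test_sphere_to_ellipsoid(self, sphere_to_ellipsoid):
        """Data term reduced >= 90% and the deformed surface voxelizes onto
        the target mask with DSC >= 0.95."""
        r = sphere_to_ellipsoid
        assert r["data_reduction"] >= 0.90
        assert r["dsc"] >= 0.95

    def test_energy_monotone_and_topology_preserved(self, sphere_to_ellipsoid):
        r = sphere_to_ellipsoid
        trace = r["trace"]
        assert all(trace[i + 1] <= trace[i] + 1e-9 for i in range(len(trace) - 1))
        assert np.array_equal(r["deformed"].faces, r["template"].faces)
        s_t = sf.mesh_summary(r["template"])
        s_d = sf.mesh_summary(r["deformed"])
        assert s_d.euler_characteristic == s_t.euler_characteristic
        assert s_d.n_components == s_t.n_components

    def test_orientation_preserved(self, sphere_to_ellipsoid):
        r = sphere_to_ellipsoid
        n0 = r["template"].face_normals()
        n1 = r["deformed"].face_normals()
        dots = np.einsum("ij,ij->i", n0, n1)
        assert (dots > 0).all()  # no normal flips past 90 degrees
        assert (r["deformed"].face_areas() > 0).all()

    def test_non_finite_momenta_rejected(self):
        mesh = hull_mesh(seed=11)
        with pytest.raises(ValueError):
            sf.DeformationPath(
                2, np.full((2, len(mesh.vertices), 3), np.nan), mesh.vertices,
                sf.KernelParams(4.0, 2.0, 0.1),
            )


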
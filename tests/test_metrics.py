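"""Overlap statistics, Geometric Laplacian roughness, outlier QC, t-test, CAP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import shapefilt as sf
from conftest import octahedron_mesh


def block_volume(slices, shape=(6, 6, 6)):
    data = np.zeros(shape, np.uint8)
    data[slices] = 1
    return sf.LabelVolume(data, np.eye(4))


class TestDSC:
    def test_identical_masks(self):
        a = block_volume((slice(1, 4),) * 3)
        assert sf.dsc(a, a) == 1.0

    def test_disjoint(self):
        a = block_volume((slice(0, 2), slice(0, 2), slice(0, 2)))
        b = block_volume((slice(4, 6), slice(4, 6), slice(4, 6)))
        assert sf.dsc(a, b) == 0.0

    def test_shifted_block_half_overlap(self):
        # 2x2x2 blocks shifted by 1 voxel in x: overlap 4, 2*4/16 = 0.5
        a = block_volume((slice(1, 3), slice(1, 3), slice(1, 3)))
        b = block_volume((slice(2, 4), slice(1, 3), slice(1, 3)))
        assert sf.dsc(a, b) == pytest.approx(0.5)

    def test_grid_mismatch(self):
        a = block_volume((slice(1, 3),) * 3)
        b = sf.LabelVolume(a.data.copy(), np.diag([2.0, 1, 1, 1]))
        with pytest.raises(sf.GeometryError):
            sf.dsc(a, b)

    def test_both_empty_warns_one(self):
        a = block_volume((slice(0, 0),) * 3)
        with pytest.warns(UserWarning):
            assert sf.dsc(a, a) == 1.0


class TestAVD:
    def test_equal_volumes(self):
        a = block_volume((slice(1, 3),) * 3)
        assert sf.avd(a, a) == 0.0

    def test_8_vs_12_voxels(self):
        a = block_volume((slice(0, 2), slice(0, 2), slice(0, 2)))  # 8
        b = block_volume((slice(0, 3), slice(0, 2), slice(0, 2)))  # 12
        assert sf.avd(a, b) == pytest.approx(0.4)

    def test_empty_vs_nonempty_is_max(self):
        a = block_volume((slice(0, 0),) * 3)
        b = block_volume((slice(1, 3),) * 3)
        assert sf.avd(a, b) == pytest.approx(2.0)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_dsc_avd_symmetry(seed):
    """DSC and AVD are symmetric in their arguments for random masks."""
    rng = np.random.default_rng(seed)
    a = sf.LabelVolume((rng.random((5, 5, 5)) < 0.4).astype(np.uint8), np.eye(4))
    b = sf.LabelVolume((rng.random((5, 5, 5)) < 0.4).astype(np.uint8), np.eye(4))
    if a.foreground_count() and b.foreground_count():
        assert sf.dsc(a, b) == pytest.approx(sf.dsc(b, a))
        assert sf.avd(a, b) == pytest.approx(sf.avd(b, a))


class TestPCC:
    def test_perfect_correlations(self):
        assert sf.pcc([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert sf.pcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_seeded_bivariate_normal(self):
        rng = np.random.default_rng(42)
        rho = 0.8
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=50)
        assert 0.6 <= sf.pcc(xy[:, 0], xy[:, 1]) <= 0.95

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sf.pcc([1, 1, 1], [1, 2, 3])


class TestGeometricLaplacian:
    def test_hexagon_center_is_zero(self):
        # center of a regular planar hexagon sits at the inverse-distance
        # weighted centroid of its ring
        ang = np.linspace(0, 2 * np.pi, 7)[:-1]
        ring = np.c_[np.cos(ang), np.sin(ang), np.zeros(6)]
        verts = np.vstack([[0, 0, 0], ring])
        faces = [[0, i, i % 6 + 1] for i in range(1, 7)]
        mesh = sf.TriMesh(verts, faces)
        assert np.allclose(sf.gl_vertex(mesh, 0), 0, atol=1e-12)

    def test_octahedron_apex(self):
        mesh = octahedron_mesh()
        gl = sf.gl_vertex(mesh, 4)  # apex (0, 0, 1): ring centroid is origin
        assert np.allclose(gl, [0, 0, 1], atol=1e-12)

    def test_scaling_homogeneity(self):
        mesh = octahedron_mesh()
        scaled = sf.TriMesh(mesh.vertices * 3.5, mesh.faces)
        assert np.allclose(
            sf.gl_vertex(scaled, 2), 3.5 * sf.gl_vertex(mesh, 2), atol=1e-12
        )

    def test_octahedron_surface_total(self):
        assert sf.gl_surface(octahedron_mesh()) == pytest.approx(6.0)

    def test_noisy_sphere_rougher_than_smooth(self):
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        smooth = sf.TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        rng = np.random.default_rng(3)
        noisy = sf.TriMesh(
            smooth.vertices + rng.normal(scale=0.3, size=smooth.vertices.shape),
            smooth.faces,
        )
        assert sf.gl_surface(noisy) > sf.gl_surface(smooth)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_invariance(self, seed):
        """GL depends only on relative vertex positions, so any proper rigid
        motion leaves it unchanged."""
        from scipy.spatial.transform import Rotation

        mesh = octahedron_mesh()
        R = Rotation.random(random_state=seed).as_matrix()
        moved = mesh.transformed(R, np.array([7.0, -3.0, 11.0]))
        ref = sf.gl_surface(mesh)
        assert sf.gl_surface(moved) == pytest.approx(ref, rel=1e-9)

    def test_degenerate_edge_is_error(self):
        verts = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]], float)
        mesh = sf.TriMesh(verts, [[0, 1, 2]])  # coincident vertices 0 and 1
        with pytest.raises(sf.DegenerateEdgeError):
            sf.gl_surface(mesh)


class TestOutlierAnalysis:
    def test_worked_example_as_printed(self):
        rep = sf.outlier_analysis([1, 2, 3, 4, 100], rule="as_printed")
        assert (rep.q1, rep.q3) == (2.0, 4.0)
        assert (rep.lower, rep.upper) == (-1.0, 5.0)
        assert rep.outlier_indices == [4]

    def test_worked_example_tukey(self):
        rep = sf.outlier_analysis([1, 2, 3, 4, 100], rule="tukey")
        assert (rep.lower, rep.upper) == (-1.0, 7.0)
        assert rep.outlier_indices == [4]

    def test_constant_values_no_outliers(self):
        for rule in ("as_printed", "tukey"):
            assert sf.outlier_analysis([5.0] * 6, rule=rule).outlier_indices == []

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            sf.outlier_analysis([1, 2, 3])


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = sf.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_means(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 50)
        y = rng.normal(5, 1, 50)
        _, p = sf.two_sample_t(x, y)
        assert p < 1e-10

    def test_matches_textbook_welch_formula(self):
        x = np.array([1.1, 2.3, 2.9])
        y = np.array([3.7, 4.1, 5.6])
        t, p = sf.two_sample_t(x, y)
        # independent hand evaluation of Welch's statistic and df
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t_ref = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 2)
        from scipy.stats import t as tdist

        p_ref = 2 * tdist.sf(abs(t_ref), df)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)


class TestCapScore:
    def test_worked_example(self):
        cap, group = sf.cap_score(40, 42)
        assert cap == pytest.approx(40 * 8.34)
        assert group == "mid-HD"

    def test_zero_cap_low_group(self):
        cap, group = sf.cap_score(50, 33.66)
        assert cap == pytest.approx(0.0)
        assert group == "low-HD"

    def test_boundaries_inclusive_to_mid(self):
        assert sf.cap_score(1.0, 290 + 33.66)[1] == "mid-HD"
        assert sf.cap_score(1.0, 368 + 33.66)[1] == "mid-HD"
        assert sf.cap_score(1.0, 368.01 + 33.66)[1] == "high-HD"
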
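import numpy as np
import pytest
import trimesh
from scipy.optimize import minimize

from skullpatch.errors import DegeneratePairError
from skullpatch.symmetry import (
    LandmarkPairs,
    Plane,
    fit_median_plane,
    mirror_mesh,
    mirror_transform,
)


def householder(origin, normal):
    """Independent closed form: reflection p -> p - 2((p-o).n)n."""
    n = np.asarray(normal) / np.linalg.norm(normal)
    m = np.eye(4)
    m[:3, :3] = np.eye(3) - 2 * np.outer(n, n)
    m[:3, 3] = 2 * (np.asarray(origin) @ n) * n
    return m


def random_plane(rng):
    n = rng.normal(size=3)
    n /= np.linalg.norm(n)
    return Plane(origin=rng.uniform(-50, 50, 3), normal=n)


class TestFitMedianPlane:
    def test_exactly_mirrored_pairs(self):
        pairs = np.array([[[-5, 1, 2], [5, 1, 2]], [[-3, 4, 0], [3, 4, 0]]], float)
        plane = fit_median_plane(LandmarkPairs(pairs))
        assert np.allclose(plane.normal, [1, 0, 0], atol=1e-12)
        assert plane.origin[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_perpendicular_bisector(self):
        plane = fit_median_plane(LandmarkPairs([[[0, 0, 0], [0, 0, 10]]]))
        assert np.allclose(plane.origin, [0, 0, 5])
        assert np.allclose(plane.normal, [0, 0, 1])

    def test_exact_symmetry_recovers_plane_to_1e6(self):
        rng = np.random.default_rng(11)
        true = random_plane(rng)
        pts = rng.uniform(-40, 40, (8, 3))
        reflected = (householder(true.origin, true.normal)[:3, :3] @ pts.T).T
        reflected += householder(true.origin, true.normal)[:3, 3]
        plane = fit_median_plane(LandmarkPairs(np.stack([pts, reflected], axis=1)))
        cosang = abs(plane.normal @ true.normal)
        assert cosang == pytest.approx(1.0, abs=1e-6)
        assert abs(plane.signed_distance(true.origin)[0]) < 1e-6

    def test_noisy_pairs_within_2_degrees_and_match_lsq_oracle(self):
        rng = np.random.default_rng(42)
        true = random_plane(rng)
        H = householder(true.origin, true.normal)
        pts = rng.uniform(-60, 60, (10, 3))
        mirrored = pts @ H[:3, :3].T + H[:3, 3]
        noisy = np.stack([pts, mirrored + rng.normal(0, 0.5, (10, 3))], axis=1)
        plane = fit_median_plane(LandmarkPairs(noisy))
        ang = np.degrees(np.arccos(min(abs(plane.normal @ true.normal), 1.0)))
        assert ang < 2.0

        # independent oracle: exhaustive least squares over plane parameters,
        # minimizing the symmetric mismatch sum |reflect(p) - q|^2
        def cost(params):
            theta, phi, d = params
            n = np.array(
                [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
            )
            Hc = householder(d * n, n)
            refl = noisy[:, 0] @ Hc[:3, :3].T + Hc[:3, 3]
            return ((refl - noisy[:, 1]) ** 2).sum()

        theta0 = np.arctan2(true.normal[1], true.normal[0])
        phi0 = np.arccos(np.clip(true.normal[2], -1, 1))
        d0 = true.origin @ true.normal
        res = minimize(cost, [theta0, phi0, d0], method="Nelder-Mead")
        th, ph, _ = res.x
        n_opt = np.array(
            [np.sin(ph) * np.cos(th), np.sin(ph) * np.sin(th), np.cos(ph)]
        )
        ang_vs_oracle = np.degrees(
            np.arccos(min(abs(plane.normal @ n_opt), 1.0))
        )
        assert ang_vs_oracle < 2.0

    def test_zero_length_pair_rejected(self):
        with pytest.raises(DegeneratePairError):
            LandmarkPairs([[[1, 2, 3], [1, 2, 3]]])


class TestMirrorTransform:
    def test_canonical_plane_x0(self):
        t = mirror_transform(Plane(origin=[0, 0, 0], normal=[1, 0, 0]))
        assert np.allclose(t.matrix[:3, :3], np.diag([-1, 1, 1]))
        assert np.allclose(t.matrix[:3, 3], 0)

    def test_plane_z5_maps_origin_to_0010(self):
        t = mirror_transform(Plane(origin=[0, 0, 5], normal=[0, 0, 1]))
        assert np.allclose(t.apply([0, 0, 0]), [0, 0, 10])

    def test_random_planes_match_householder_and_are_involutive_isometries(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            plane = random_plane(rng)
            t = mirror_transform(plane)
            assert np.allclose(
                t.matrix, householder(plane.origin, plane.normal), atol=1e-9
            )
            assert np.allclose(t.matrix @ t.matrix, np.eye(4), atol=1e-9)
            assert np.linalg.det(t.matrix[:3, :3]) == pytest.approx(-1, abs=1e-9)
            p, q = rng.uniform(-100, 100, (2, 3))
            assert np.allclose(t.apply(t.apply(p)), p, atol=1e-9)
            assert np.linalg.norm(t.apply(p) - t.apply(q)) == pytest.approx(
                np.linalg.norm(p - q), abs=1e-9
            )

    def test_factor_product_equals_matrix(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = mirror_transform(random_plane(rng))
            assert len(t.factors) == 5
            assert np.allclose(np.linalg.multi_dot(t.factors), t.matrix, atol=1e-9)

    def test_antiparallel_normal_tie_break(self):
        t = mirror_transform(Plane(origin=[1, 2, 3], normal=[-1, 0, 0]))
        assert np.allclose(t.matrix @ t.matrix, np.eye(4), atol=1e-9)
        assert np.allclose(t.apply([1, 5, 5]), [1, 5, 5])  # point on plane fixed

    def test_non_unit_normal_warns_and_normalizes(self):
        plane = Plane(origin=[0, 0, 0], normal=[1, 0, 0])
        plane.normal = np.array([2.0, 0.0, 0.0])  # bypass dataclass normalization
        with pytest.warns(UserWarning):
            t = mirror_transform(plane)
        assert np.allclose(t.matrix[:3, :3], np.diag([-1, 1, 1]))

    def test_rotation_variant_is_proper_rotation(self):
        t = mirror_transform(
            Plane(origin=[0, 0, 0], normal=[0, 1, 0]), rotation_variant=True
        )
        assert np.linalg.det(t.matrix[:3, :3]) == pytest.approx(1.0, abs=1e-9)


def signed_volume(mesh):
    """Independent divergence-theorem volume: sum of signed tetrahedra."""
    v = mesh.vertices[mesh.faces]
    return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6)


class TestMirrorMesh:
    def test_involution(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=7.0)
        mesh.apply_translation([3, -2, 5])
        t = mirror_transform(Plane(origin=[1, 1, 1], normal=[1, 2, 3]))
        twice = mirror_mesh(mirror_mesh(mesh, t), t)
        assert np.allclose(twice.vertices, mesh.vertices, atol=1e-9)
        assert np.array_equal(twice.faces, mesh.faces)

    def test_symmetric_mesh_maps_to_itself_as_point_set(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        t = mirror_transform(Plane(origin=[0, 0, 0], normal=[1, 0, 0]))
        mirrored = mirror_mesh(mesh, t)
        from skullpatch.evaluate import distance_field

        assert distance_field(mirrored, mesh).max < 1e-6
        assert distance_field(mesh, mirrored).max < 1e-6

    def test_signed_volume_preserved_by_face_reversal(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        mesh.apply_translation([10, 0, 0])
        t = mirror_transform(Plane(origin=[2, 0, 0], normal=[1, 0, 0]))
        mirrored = mirror_mesh(mesh, t)
        assert signed_volume(mirrored) == pytest.approx(signed_volume(mesh), rel=1e-9)

    def test_preserves_areas_and_edge_lengths(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=4.0)
        t = mirror_transform(Plane(origin=[0, 1, 0], normal=[0, 1, 1]))
        mirrored = mirror_mesh(mesh, t)
        assert np.allclose(mirrored.area_faces, mesh.area_faces, atol=1e-9)
        e0 = np.linalg.norm(np.diff(mesh.vertices[mesh.edges_unique], axis=1))
        e1 = np.linalg.norm(np.diff(mirrored.vertices[mirrored.edges_unique], axis=1))
        assert e0 == pytest.approx(e1, abs=1e-9)
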
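import numpy as np
import pytest
import trimesh

from skullpatch.clip import Contour3D
from skullpatch.errors import SelfIntersectionError, TopologyError, ZeroAreaError
from skullpatch.evaluate import voxel_grid, voxelize_solid
from skullpatch.implant import (
    boundary_loops,
    build_final_implant,
    build_initial_implant,
    offset_surface,
    ruled_wall,
)

from .conftest import icosphere, ring_contour, spherical_cap_patch


def flat_disc_patch(radius=20.0, n_ring=48, n_radial=12):
    """Triangulated flat disc in the z=0 plane, normals +z."""
    from scipy.spatial import Delaunay

    pts = [np.zeros(2)]
    for i in range(1, n_radial + 1):
        r = radius * i / n_radial
        k = max(int(n_ring * i / n_radial), 6)
        a = np.linspace(0, 2 * np.pi, k, endpoint=False) + 0.1 * i
        pts.append(np.column_stack([r * np.cos(a), r * np.sin(a)]))
    p2 = np.vstack(pts)
    tri = Delaunay(p2)
    v = np.column_stack([p2, np.zeros(len(p2))])
    faces = tri.simplices
    a, b, c = p2[faces[:, 0]], p2[faces[:, 1]], p2[faces[:, 2]]
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    faces[cross < 0] = faces[cross < 0][:, ::-1]
    return trimesh.Trimesh(v, faces, process=False)


def disc_contour(radius=20.0, n=64):
    return Contour3D(ring_contour(radius, None, n=n))


class TestOffsetSurface:
    def test_flat_square_translates(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        sq = trimesh.Trimesh(v, [[0, 1, 2], [0, 2, 3]], process=False)
        out = offset_surface(sq, 2.0)
        assert np.allclose(out.vertices, v - [0, 0, 2.0], atol=1e-12)

    def test_sphere_offsets_to_concentric_radius(self):
        sphere = icosphere(radius=20.0, subdivisions=4)
        out = offset_surface(sphere, 2.0)
        radii = np.linalg.norm(out.vertices, axis=1)
        assert np.all(np.abs(radii - 18.0) < 0.01)

    def test_cap_area_ratio_matches_concentric_oracle(self):
        r, t = 20.0, 2.0
        cap = spherical_cap_patch(radius=r, cap_angle_deg=30.0, subdivisions=5)
        out = offset_surface(cap, t)
        assert out.area / cap.area == pytest.approx((r - t) ** 2 / r**2, rel=0.02)

    def test_excessive_thickness_raises_with_faces(self):
        # dome with apex curvature radius ~0.17 mm: a 1 mm offset must
        # push the apex past its center of curvature and invert faces
        from scipy.spatial import Delaunay

        xs = np.linspace(-1, 1, 15)
        X, Y = np.meshgrid(xs, xs)
        p2 = np.column_stack([X.ravel(), Y.ravel()])
        tri = Delaunay(p2)
        faces = tri.simplices
        a, b, c = p2[faces[:, 0]], p2[faces[:, 1]], p2[faces[:, 2]]
        cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
            c[:, 0] - a[:, 0]
        )
        faces[cross < 0] = faces[cross < 0][:, ::-1]
        dome = trimesh.Trimesh(
            np.column_stack([p2, -3.0 * (p2**2).sum(axis=1)]), faces, process=False
        )
        with pytest.raises(SelfIntersectionError) as exc:
            offset_surface(dome, 1.0)
        assert len(exc.value.face_indices) > 0


class TestRuledWall:
    def test_cylinder_wall_area(self):
        a = Contour3D(ring_contour(1.0, None, n=32))
        b = Contour3D(ring_contour(1.0, None, n=32) + [0, 0, 2.0])
        wall = ruled_wall(a, b)
        assert len(wall.faces) == 64
        assert wall.area == pytest.approx(2 * np.pi * 1.0 * 2.0, rel=0.02)

    def test_identical_loops_zero_area(self):
        a = Contour3D(ring_contour(1.0, None, n=16))
        with pytest.raises(ZeroAreaError):
            ruled_wall(a, Contour3D(a.points.copy()))

    def test_square_loops_8_triangles(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        wall = ruled_wall(Contour3D(sq), Contour3D(sq + [0, 0, 2.0]), n=4)
        assert len(wall.faces) == 8
        assert len(boundary_loops(wall)) == 2  # closed strip: two rims

    def test_opposite_winding_auto_reversed(self):
        a = Contour3D(ring_contour(1.0, None, n=16))
        b = Contour3D((ring_contour(1.0, None, n=16) + [0, 0, 2.0])[::-1])
        with pytest.warns(UserWarning):
            wall = ruled_wall(a, b)
        assert wall.area == pytest.approx(2 * np.pi * 2.0, rel=0.05)


def solid_checks(solid):
    assert solid.mesh.is_watertight
    assert solid.mesh.euler_number == 2
    assert solid.volume > 0


class TestBuildInitialImplant:
    def test_flat_disc_prism_volume(self):
        disc = flat_disc_patch(radius=20.0)
        solid = build_initial_implant(disc, disc_contour(20.0), thickness=2.0)
        solid_checks(solid)
        assert solid.volume == pytest.approx(disc.area * 2.0, rel=0.02)

    def test_spherical_cap_shell_volume(self):
        r, t, ang = 80.0, 4.0, 30.0
        cap = spherical_cap_patch(radius=r, cap_angle_deg=ang, subdivisions=5)
        rim = Contour3D(ring_contour(None, ang, n=128, sphere_radius=r))
        solid = build_initial_implant(cap, rim, thickness=t)
        solid_checks(solid)
        shell = (
            2 * np.pi / 3 * (1 - np.cos(np.radians(ang))) * (r**3 - (r - t) ** 3)
        )
        # the discrete cap is clipped along whole triangles, so compare
        # against the cone angle of its actual boundary
        cos_actual = (
            np.asarray(cap.vertices)[boundary_loops(cap)[0]][:, 2].mean() / r
        )
        shell_actual = 2 * np.pi / 3 * (1 - cos_actual) * (r**3 - (r - t) ** 3)
        assert solid.volume == pytest.approx(shell_actual, rel=0.03)
        assert solid.volume == pytest.approx(shell, rel=0.10)

    def test_provenance_labels_partition_faces(self):
        disc = flat_disc_patch(radius=10.0)
        solid = build_initial_implant(disc, disc_contour(10.0), thickness=3.0)
        labels, counts = np.unique(solid.provenance, return_counts=True)
        assert set(labels) == {"inner", "outer", "wall"}
        assert counts.sum() == len(solid.mesh.faces)
        assert len(solid.outer_surface.faces) == len(disc.faces)

    def test_multi_boundary_surface_rejected(self):
        disc = flat_disc_patch(radius=10.0)
        # punch a hole: remove faces near the center -> annulus, 2 loops
        keep = np.linalg.norm(disc.triangles_center[:, :2], axis=1) > 3.0
        annulus = disc.submesh([np.where(keep)[0]], append=True)
        with pytest.raises(TopologyError):
            build_initial_implant(annulus, disc_contour(10.0), thickness=2.0)

    def test_thin_shell_volume_area_relation(self):
        cap = spherical_cap_patch(radius=60.0, cap_angle_deg=25.0, subdivisions=4)
        rim = Contour3D(ring_contour(None, 25.0, n=96, sphere_radius=60.0))
        t = 2.0
        solid = build_initial_implant(cap, rim, thickness=t)
        assert solid.volume == pytest.approx(cap.area * t, rel=0.05)

    def test_divergence_volume_matches_voxelized(self):
        disc = flat_disc_patch(radius=15.0)
        solid = build_initial_implant(disc, disc_contour(15.0), thickness=4.0)
        axes = voxel_grid(solid.mesh.bounds, 0.5)
        vox = voxelize_solid(solid.mesh, axes).sum() * 0.5**3
        assert solid.volume == pytest.approx(vox, rel=0.02)


class TestBuildFinalImplant:
    def cap_fixture(self, r=60.0, ang=30.0, t=3.0):
        cap = spherical_cap_patch(radius=r, cap_angle_deg=ang, subdivisions=4)
        rim_pts = np.asarray(cap.vertices)[boundary_loops(cap)[0]]
        rim = Contour3D(rim_pts)
        skull = icosphere(radius=r, subdivisions=4)
        initial = build_initial_implant(cap, rim, thickness=t)
        return cap, rim, skull, initial

    def test_same_contour_is_identity(self):
        _, rim, skull, initial = self.cap_fixture()
        final = build_final_implant(initial, skull, rim)
        assert len(final.mesh.vertices) == len(initial.mesh.vertices)
        d = np.linalg.norm(
            np.asarray(final.mesh.vertices) - np.asarray(initial.mesh.vertices), axis=1
        )
        assert d.max() < 1e-6

    def test_shrunk_contour_reduces_footprint(self):
        r, ang = 60.0, 30.0
        _, rim, skull, initial = self.cap_fixture(r=r, ang=ang)
        smaller = Contour3D(ring_contour(None, ang - 8.0, n=96, sphere_radius=r))
        final = build_final_implant(initial, skull, smaller)
        solid_checks(final)
        assert final.outer_surface.area < initial.outer_surface.area
        assert final.rim_distance_mm["mean"] < 1.0

    def test_idempotent_reclipping(self):
        r, ang = 60.0, 30.0
        _, rim, skull, initial = self.cap_fixture(r=r, ang=ang)
        smaller = Contour3D(ring_contour(None, ang - 8.0, n=96, sphere_radius=r))
        final1 = build_final_implant(initial, skull, smaller)
        final2 = build_final_implant(final1, skull, smaller)
        assert len(final1.mesh.vertices) == len(final2.mesh.vertices)
        d = np.linalg.norm(
            np.asarray(final1.mesh.vertices) - np.asarray(final2.mesh.vertices),
            axis=1,
        )
        assert d.max() < 1e-6
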
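"""Surface fitting over the defect: projection dedup + Delaunay triangulation.

The clipped patch of the mirrored skull is a noisy, possibly multi-sheet
point set. It is regularized exactly the way an interactive viewer does it:
points are orthographically projected to integer display cells (floor of
projected mm / pixel pitch); within each cell only the point nearest the
viewer survives. The surviving points are Delaunay-triangulated in the
projection plane, triangles whose projected centroid falls outside the
projected selection contour are discarded, and every vertex keeps its
original world coordinates — the fitted surface interpolates the retained
input points exactly.

The camera convention: ``view_direction`` points from the surface toward
the viewer, so "nearest" means largest coordinate along it. The default
camera for a selection loop looks back along the loop's mean-normal
direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .clip import Contour3D
from .errors import DegenerateTriangulationError, InsufficientPointsError

__all__ = ["ViewCamera", "FitPointSet", "default_camera", "project_dedup", "delaunay_fit"]


@dataclass
class ViewCamera:
    """Orthographic camera: direction toward the viewer, up vector, mm/pixel."""

    view_direction: np.ndarray
    up: np.ndarray
    pixel_pitch: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.view_direction, dtype=float).reshape(3)
        w = w / np.linalg.norm(w)
        up = np.asarray(self.up, dtype=float).reshape(3)
        up = up - (up @ w) * w  # orthogonalize against the view direction
        n = np.linalg.norm(up)
        if n < 1e-12:
            raise ValueError("up vector parallel to view direction")
        self.view_direction = w
        self.up = up / n
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def basis(self) -> tuple:
        """Right-handed (right, up, toward-viewer) display basis."""
        v = self.up
        w = self.view_direction
        u = np.cross(v, w)
        return u, v, w

    def to_display(self, points: np.ndarray) -> np.ndarray:
        """Continuous 2D display coordinates (mm / pitch) of world points."""
        u, v, _ = self.basis
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.column_stack([pts @ u, pts @ v]) / self.pixel_pitch

    def depth(self, points: np.ndarray) -> np.ndarray:
        """Coordinate along the viewer direction; larger = nearer."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.view_direction


def default_camera(direction: np.ndarray, pixel_pitch: float = 1.0) -> ViewCamera:
    """Camera looking at the patch along a selection loop's direction."""
    direction = np.asarray(direction, dtype=float)
    up = np.cross(direction / np.linalg.norm(direction), [0.0, 0.0, 1.0])
    if np.linalg.norm(up) < 1e-9:
        up = np.array([1.0, 0.0, 0.0])
    return ViewCamera(view_direction=direction, up=up, pixel_pitch=pixel_pitch)


@dataclass
class FitPointSet:
    """Deduplicated fit points: world coordinates plus their display cells."""

    world_points: np.ndarray
    display_points: np.ndarray
    n_input: int

    def __post_init__(self):
        self.world_points = np.asarray(self.world_points, dtype=float)
        self.display_points = np.asarray(self.display_points, dtype=np.int64)
        if len(self.world_points) != len(self.display_points):
            raise ValueError("world and display point counts differ")

    def __len__(self):
        return len(self.world_points)


def project_dedup(points: np.ndarray, cam: ViewCamera) -> FitPointSet:
    """Project points to integer display cells and keep one per cell.

    Within a cell the survivor is the point nearest the viewer (largest
    depth); exact depth ties keep the first occurrence.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        raise InsufficientPointsError("need at least 3 points to fit a surface")
    cells = np.floor(cam.to_display(points)).astype(np.int64)
    depth = cam.depth(points)
    # collapse 2D cells to a single sortable key
    cmin = cells.min(axis=0)
    span = cells.max(axis=0) - cmin + 1
    key = (cells[:, 0] - cmin[0]) * span[1] + (cells[:, 1] - cmin[1])
    order = np.lexsort((np.arange(len(points)), -depth, key))
    sorted_key = key[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = sorted_key[1:] != sorted_key[:-1]
    kept = order[first]
    kept.sort()  # stable: preserve input order of survivors
    if len(kept) < 3:
        raise InsufficientPointsError(
            f"only {len(kept)} points survive display dedup; need >= 3"
        )
    return FitPointSet(
        world_points=points[kept], display_points=cells[kept], n_input=len(points)
    )


def _min_separation_keep(pts2d: np.ndarray, tol: float) -> np.ndarray:
    """Greedy first-come filter enforcing a minimum pairwise 2D separation.

    Cell-based dedup still allows survivors arbitrarily close across cell
    borders; triangulating such pairs yields sliver triangles that break
    the downstream offset. Deterministic: earlier points win.
    """
    from scipy.spatial import cKDTree

    if tol <= 0:
        return np.ones(len(pts2d), dtype=bool)
    pairs = cKDTree(pts2d).query_pairs(tol, output_type="ndarray")
    keep = np.ones(len(pts2d), dtype=bool)
    if len(pairs):
        pairs.sort(axis=1)
        order = np.lexsort((pairs[:, 0], pairs[:, 1]))
        for lo, hi in pairs[order]:
            if keep[lo] and keep[hi]:
                keep[hi] = False
    return keep


def delaunay_fit(
    fps: FitPointSet,
    contour: Contour3D,
    cam: ViewCamera,
    coverage_warn: float = 0.99,
    merge_tolerance: float = 0.5,
) -> trimesh.Trimesh:
    """Triangulate the deduplicated points over the selection contour.

    2D Delaunay triangulation of the projected points; triangles whose
    projected centroid lies outside the projected contour polygon are
    discarded. Vertices keep their world coordinates. Face winding is chosen
    so normals point toward the viewer (outward for a patch selected along
    its outward normal).

    ``merge_tolerance`` (in display pixels) drops points that project
    closer than that to an already-kept point, the same role as the merge
    tolerance of interactive Delaunay filters; it bounds the sliver quality
    of the triangulation.

    Emits a warning when the retained triangles cover less than
    ``coverage_warn`` of the projected contour area — the symptom of a
    strongly non-convex defect the projection-based fit cannot handle.
    """
    disp = cam.to_display(fps.world_points)
    kept = _min_separation_keep(disp, merge_tolerance)
    if kept.sum() < 3:
        raise DegenerateTriangulationError("fewer than 3 points after merge")
    fps = FitPointSet(
        world_points=fps.world_points[kept],
        display_points=fps.display_points[kept],
        n_input=fps.n_input,
    )
    pts2d = disp[kept] * cam.pixel_pitch
    centered = pts2d - pts2d.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[1] < 1e-9:
        raise DegenerateTriangulationError("projected points are collinear")
    tri = Delaunay(pts2d)
    simplices = tri.simplices
    poly = Polygon(cam.to_display(contour.points) * cam.pixel_pitch)
    if not poly.is_valid:
        poly = poly.buffer(0)
    centroids = pts2d[simplices].mean(axis=1)
    import shapely

    inside = shapely.contains(poly, shapely.points(centroids))
    faces = simplices[inside]
    if len(faces) == 0:
        raise DegenerateTriangulationError("no triangle centroid inside the contour")
    # enforce CCW in display coords -> normal toward the viewer
    a, b, c = pts2d[faces[:, 0]], pts2d[faces[:, 1]], pts2d[faces[:, 2]]
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    faces[cross < 0] = faces[cross < 0][:, ::-1]

    covered = float(
        np.abs(
            0.5
            * (
                (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
            )
        ).sum()
    )
    if poly.area > 0 and covered < coverage_warn * poly.area:
        warnings.warn(
            f"fitted surface covers only {covered / poly.area:.1%} of the contour "
            "area; the defect region may be non-convex",
            stacklevel=2,
        )
    mesh = trimesh.Trimesh(vertices=fps.world_points, faces=faces, process=False)
    mesh = _clean_patch(mesh)
    mesh.remove_unreferenced_vertices()
    return mesh


def _clean_patch(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Reduce a triangulated patch to a single disk-like sheet.

    Contour filtering can leave multiple components or "pinch" vertices
    where two regions meet at a single vertex; such a boundary cannot be
    walked as simple loops and cannot be closed by a ruled wall. Keep the
    largest face-connected component and delete the faces at pinch vertices
    until the boundary is a set of simple loops.
    """
    while True:
        comps = trimesh.graph.connected_components(
            mesh.face_adjacency, nodes=np.arange(len(mesh.faces))
        )
        largest = max(comps, key=len)
        if len(largest) < len(mesh.faces):
            mesh = mesh.submesh([largest], append=True)
        edges = mesh.edges
        unique = trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)
        boundary = edges[unique]
        starts, counts = np.unique(boundary[:, 0], return_counts=True)
        pinch = starts[counts > 1]
        if len(pinch) == 0:
            return _fill_interior_holes(mesh)
        bad = np.isin(mesh.faces, pinch).any(axis=1)
        if bad.all():
            raise DegenerateTriangulationError(
                "patch collapses entirely while removing pinch vertices"
            )
        mesh = mesh.submesh([np.where(~bad)[0]], append=True)


def _fill_interior_holes(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Close every boundary loop except the longest with a triangle fan.

    A jagged selection contour can drop isolated interior triangles of the
    Delaunay patch, leaving small holes; the solidification step requires a
    single boundary loop. Fans reuse existing vertices only, wound so the
    new faces mate with the directed boundary edges.
    """
    from .implant import boundary_loops

    loops = boundary_loops(mesh)
    if len(loops) <= 1:
        return mesh
    loops = sorted(loops, key=len, reverse=True)
    extra = []
    for hole in loops[1:]:
        v0 = hole[0]
        for a, b in zip(hole[1:-1], hole[2:]):
            extra.append((v0, b, a))
    if not extra:
        return mesh
    faces = np.vstack([mesh.faces, np.asarray(extra, dtype=np.int64)])
    return trimesh.Trimesh(vertices=mesh.vertices.copy(), faces=faces, process=False)
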
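"""Solidification of the fitted surface into a printable implant.

The fitted patch is turned into a closed solid by the classic three-sheet
construction: the patch itself is the outer surface, an inward offset along
the (angle-weighted) vertex normals is the inner surface, and a ruled
triangle strip between the two boundary loops closes the side wall. The
boundary vertices of outer and inner sheets correspond index-by-index (the
offset preserves connectivity), so the assembled mesh is exactly watertight
with no vertex welding.

The final implant is the same construction applied after re-clipping the
outer sheet with the defect-edge contour drawn on the skull, so the implant
rim follows the actual defect margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .clip import Contour3D, build_loop_implicit, clip_mesh
from .errors import SelfIntersectionError, TopologyError, ZeroAreaError

__all__ = [
    "ImplantSolid",
    "offset_surface",
    "ruled_wall",
    "build_initial_implant",
    "build_final_implant",
    "boundary_loops",
    "smooth_open_surface",
]


@dataclass
class ImplantSolid:
    """A watertight implant with per-face provenance (outer / inner / wall)."""

    mesh: trimesh.Trimesh
    thickness: float
    provenance: np.ndarray
    rim_distance_mm: dict | None = None

    def __post_init__(self):
        self.provenance = np.asarray(self.provenance)
        if len(self.provenance) != len(self.mesh.faces):
            raise ValueError("one provenance label per face required")

    def _sheet(self, label: str) -> trimesh.Trimesh:
        sub = self.mesh.submesh([np.where(self.provenance == label)[0]], append=True)
        sub.remove_unreferenced_vertices()
        return sub

    @property
    def outer_surface(self) -> trimesh.Trimesh:
        return self._sheet("outer")

    @property
    def inner_surface(self) -> trimesh.Trimesh:
        return self._sheet("inner")

    @property
    def wall(self) -> trimesh.Trimesh:
        return self._sheet("wall")

    @property
    def volume(self) -> float:
        return float(self.mesh.volume)

    def export_stl(self, path) -> None:
        self.mesh.export(path, file_type="stl")


def boundary_loops(mesh: trimesh.Trimesh) -> list:
    """Ordered boundary loops as lists of vertex indices.

    Each loop follows the directed boundary edges, i.e. it is wound
    consistently with the face orientation (surface to the left).
    """
    edges = mesh.edges
    unique_idx = trimesh.grouping.group_rows(mesh.edges_sorted, require_count=1)
    boundary = edges[unique_idx]
    succ = {int(a): int(b) for a, b in boundary}
    loops = []
    visited = set()
    for start in sorted(succ):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = succ[start]
        while cur != start:
            if cur in visited or cur not in succ:
                raise TopologyError("boundary is not a set of simple loops")
            loop.append(cur)
            visited.add(cur)
            cur = succ[cur]
        loops.append(loop)
    return loops


def _smooth_normal_field(surface: trimesh.Trimesh, iterations: int) -> np.ndarray:
    """Angle-weighted vertex normals, relaxed by neighbor averaging.

    Surface meshes coming out of the projection/Delaunay stage contain
    near-degenerate triangles whose raw normals are ill-conditioned; a few
    rounds of normalized neighbor averaging give a smooth offset direction
    field without changing any vertex position.
    """
    normals = np.array(surface.vertex_normals, dtype=float)
    if iterations <= 0:
        return normals
    edges = surface.edges_unique
    deg = np.zeros(len(normals))
    np.add.at(deg, edges[:, 0], 1.0)
    np.add.at(deg, edges[:, 1], 1.0)
    deg[deg == 0] = 1.0
    for _ in range(iterations):
        acc = np.zeros_like(normals)
        np.add.at(acc, edges[:, 0], normals[edges[:, 1]])
        np.add.at(acc, edges[:, 1], normals[edges[:, 0]])
        normals = 0.5 * normals + 0.5 * acc / deg[:, None]
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm < 1e-12] = 1.0
        normals = normals / norm
    return normals


def offset_surface(
    surface: trimesh.Trimesh,
    thickness: float,
    normal_smoothing: int = 0,
    sliver_fraction: float = 0.1,
) -> trimesh.Trimesh:
    """Offset every vertex by ``-thickness`` along its vertex normal.

    Vertex normals are trimesh's angle-weighted average of incident face
    normals, optionally relaxed by ``normal_smoothing`` rounds of neighbor
    averaging (needed for jagged isosurface-derived patches; a smooth normal
    field moves skinny triangles near-rigidly instead of shearing them).
    Connectivity is unchanged. Raises if the offset inverts any face of
    representative size (thickness too large for the local curvature).
    Sliver faces — area below ``sliver_fraction`` of the median face area —
    flip under arbitrarily small perturbations (they are cut fragments from
    contour clipping, with no reliable orientation of their own) and are
    excluded from the inversion check.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    normals = _smooth_normal_field(surface, normal_smoothing)
    verts = surface.vertices - thickness * normals
    out = trimesh.Trimesh(vertices=verts, faces=surface.faces.copy(), process=False)
    dots = np.einsum("ij,ij->i", out.face_normals, surface.face_normals)
    areas = surface.area_faces
    checkable = areas > max(sliver_fraction * float(np.median(areas)), 1e-12)
    flipped = np.where((dots <= 0) & checkable)[0]
    if len(flipped):
        raise SelfIntersectionError(
            f"offset of {thickness} mm inverts {len(flipped)} faces",
            face_indices=flipped,
        )
    return out


def ruled_wall(
    loop_outer: Contour3D, loop_inner: Contour3D, n: int | None = None
) -> trimesh.Trimesh:
    """Triangle strip (ruled surface) between two closed loops.

    Both loops are arc-length resampled to ``n`` points (default: the larger
    of the two counts) and connected index-to-index, producing exactly 2n
    triangles. Loops with opposite winding are auto-reversed with a warning;
    coincident loops are rejected.
    """
    if n is None:
        n = max(len(loop_outer), len(loop_inner))
    outer = loop_outer.resample(n).points
    inner = loop_inner.resample(n).points

    def loop_normal(pts):
        # Newell's formula
        nxt = np.roll(pts, -1, axis=0)
        return np.cross(pts, nxt).sum(axis=0)

    n_o, n_i = loop_normal(outer), loop_normal(inner)
    if n_o @ n_i < 0:
        warnings.warn("inner loop wound opposite to outer; reversing", stacklevel=2)
        inner = inner[::-1]
    verts = np.vstack([outer, inner])
    idx = np.arange(n)
    nxt = (idx + 1) % n
    # quad (o_i, o_{i+1}) x (in_i, in_{i+1}) -> (o_i, in_i, in_{i+1}), (o_i, in_{i+1}, o_{i+1})
    f1 = np.column_stack([idx, idx + n, nxt + n])
    f2 = np.column_stack([idx, nxt + n, nxt])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.vstack([f1, f2]), process=False)
    if mesh.area < 1e-9:
        raise ZeroAreaError("loops coincide; ruled wall has zero area")
    return mesh


def smooth_open_surface(
    surface: trimesh.Trimesh,
    lam: float = 0.5,
    mu: float = -0.53,
    iterations: int = 10,
) -> trimesh.Trimesh:
    """Taubin smoothing (umbrella operator) with boundary vertices fixed.

    Each iteration applies a positive (``lam``) then a negative (``mu``)
    Laplacian step; the negative step compensates the shrinkage/flattening
    of plain Laplacian smoothing, so a thin implant keeps its thickness
    while high-frequency ripple is removed. ``mu=0`` recovers the plain
    Laplacian filter.
    """
    verts = surface.vertices.copy()
    edges = surface.edges_unique
    boundary_idx = set()
    for loop in boundary_loops(surface):
        boundary_idx.update(loop)
    free = np.ones(len(verts), dtype=bool)
    free[list(boundary_idx)] = False
    n = len(verts)
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1.0)
    np.add.at(deg, edges[:, 1], 1.0)
    deg[deg == 0] = 1.0

    def step(factor):
        acc = np.zeros_like(verts)
        np.add.at(acc, edges[:, 0], verts[edges[:, 1]])
        np.add.at(acc, edges[:, 1], verts[edges[:, 0]])
        delta = acc / deg[:, None] - verts
        verts[free] += factor * delta[free]

    for _ in range(iterations):
        step(lam)
        if mu != 0.0:
            step(mu)
    return trimesh.Trimesh(vertices=verts, faces=surface.faces.copy(), process=False)


def _assemble_solid(outer: trimesh.Trimesh, inner_verts: np.ndarray, thickness: float):
    """Weld outer sheet, offset inner sheet and index-matched wall into a solid."""
    loops = boundary_loops(outer)
    if len(loops) != 1:
        raise TopologyError(
            f"fitted surface has {len(loops)} boundary loops; exactly 1 required"
        )
    loop = loops[0]
    n_out = len(outer.vertices)
    verts = np.vstack([outer.vertices, inner_verts])
    outer_faces = np.asarray(outer.faces)
    inner_faces = outer_faces[:, ::-1] + n_out  # reversed: outward is inward side
    wall = []
    for a, b in zip(loop, loop[1:] + loop[:1]):
        wall.append((a, a + n_out, b + n_out))
        wall.append((a, b + n_out, b))
    wall = np.asarray(wall, dtype=np.int64)
    faces = np.vstack([outer_faces, inner_faces, wall])
    provenance = np.concatenate(
        [
            np.repeat("outer", len(outer_faces)),
            np.repeat("inner", len(inner_faces)),
            np.repeat("wall", len(wall)),
        ]
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return ImplantSolid(mesh=mesh, thickness=thickness, provenance=provenance)


def build_initial_implant(
    fitted: trimesh.Trimesh,
    contour: Contour3D,
    thickness: float = 4.0,
    smooth_inner: bool = True,
    normal_smoothing: int = 10,
) -> ImplantSolid:
    """Solidify the fitted surface: outer sheet, inner offset, ruled wall.

    ``contour`` is the selection contour the surface was fitted over (kept
    for provenance/reporting; the wall follows the fitted surface's own
    boundary loop, which is its discrete realization). The inner sheet is
    optionally Laplacian-smoothed (boundary fixed) to give the implant the
    smooth inner face that sits against the dura.
    """
    inner = offset_surface(fitted, thickness, normal_smoothing=normal_smoothing)
    if smooth_inner:
        inner = smooth_open_surface(inner, lam=0.5, iterations=10)
    solid = _assemble_solid(fitted, np.asarray(inner.vertices), thickness)
    if not solid.mesh.is_watertight:
        raise TopologyError("assembled implant is not watertight")
    return solid


def build_final_implant(
    initial: ImplantSolid,
    skull: trimesh.Trimesh,
    edge_contour: Contour3D,
    thickness: float | None = None,
    smooth_inner: bool = True,
    rim_tolerance: float = 1.0,
) -> ImplantSolid:
    """Re-clip the implant's outer sheet to the defect-edge contour and re-solidify.

    Node normals for the edge contour are looked up from the skull surface
    (nearest vertex). After re-solidification the implant rim is checked to
    lie within ``rim_tolerance`` mm (mean distance) of the edge contour; a
    warning is emitted otherwise.
    """
    if thickness is None:
        thickness = initial.thickness
    tree = cKDTree(skull.vertices)
    _, nearest = tree.query(edge_contour.points)
    normals = np.asarray(skull.vertex_normals)[nearest]
    loop = build_loop_implicit(edge_contour, normals)
    outer = initial.outer_surface
    clipped = clip_mesh(outer, loop)
    from .fit import _clean_patch  # shared disk-topology cleanup

    clipped = _clean_patch(clipped)
    final = build_initial_implant(
        clipped, edge_contour, thickness=thickness, smooth_inner=smooth_inner
    )
    rim = final.outer_surface
    rim_loop = boundary_loops(rim)[0]
    rim_pts = np.asarray(rim.vertices)[rim_loop]
    d = _polyline_distance(rim_pts, edge_contour.points)
    final.rim_distance_mm = {"mean": float(d.mean()), "max": float(d.max())}
    if d.mean() > rim_tolerance:
        warnings.warn(
            f"final rim mean distance {d.mean():.2f} mm exceeds tolerance "
            f"{rim_tolerance} mm",
            stacklevel=2,
        )
    return final


def _polyline_distance(points: np.ndarray, loop_points: np.ndarray) -> np.ndarray:
    """Distance from each point to a closed polyline (exact per-segment)."""
    a = loop_points
    b = np.roll(loop_points, -1, axis=0)
    ab = b - a  # (m, 3)
    ap = points[:, None, :] - a[None, :, :]  # (n, m, 3)
    denom = np.einsum("mj,mj->m", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / denom, 0.0, 1.0)
    proj = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)
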
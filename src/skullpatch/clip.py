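"""Implicit selection loops and contour-based mesh clipping.

A closed 3D contour drawn around the defect defines an implicit function:
the contour is projected along its mean surface-normal direction onto the
plane through its centroid, and the implicit value of a query point is the
signed 2D distance from the point's projection to the polygon boundary —
negative strictly inside, positive strictly outside, zero on the boundary.
The zero level set is therefore the infinite prism through the loop; axial
distance is deliberately ignored, which is what makes the loop act as a
selection tool on a curved surface.

``clip_mesh`` keeps the sub-mesh with implicit value <= 0, splitting
boundary-crossing triangles along the zero level by linear interpolation of
the vertex values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from shapely.geometry import LinearRing, Polygon

from .errors import (
    DegenerateDirectionError,
    EmptyClipError,
    InvalidContourError,
)

__all__ = [
    "Contour3D",
    "LoopImplicit",
    "plane_basis",
    "build_loop_implicit",
    "implicit_value",
    "implicit_values",
    "clip_mesh",
    "nearest_component",
]


def plane_basis(direction: np.ndarray) -> tuple:
    """Right-handed orthonormal (u, v, w) with w = normalized direction.

    u is chosen as normalize(direction x ẑ), falling back to x̂ when the
    direction is (anti)parallel to ẑ; deterministic by construction.
    """
    w = np.asarray(direction, dtype=float)
    w = w / np.linalg.norm(w)
    u = np.cross(w, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-9:
        u = np.array([1.0, 0.0, 0.0])
    u = u - (u @ w) * w
    u = u / np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


@dataclass
class Contour3D:
    """Closed ordered 3D polyline (implicitly last-to-first), world mm."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 3:
            raise InvalidContourError("contour needs >= 3 points of dimension 3")
        if not np.isfinite(self.points).all():
            raise InvalidContourError("contour coordinates must be finite")
        closed_diff = np.diff(
            np.vstack([self.points, self.points[:1]]), axis=0
        )
        if np.any(np.linalg.norm(closed_diff, axis=1) < 1e-12):
            raise InvalidContourError("consecutive contour points must be distinct")
        centered = self.points - self.points.mean(axis=0)
        if np.linalg.svd(centered, compute_uv=False)[1] < 1e-9:
            raise InvalidContourError("contour points are collinear")

    def __len__(self):
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def resample(self, n: int) -> "Contour3D":
        """Arc-length resampling of the closed loop to exactly n points.

        Returns the contour unchanged when n equals the current count, so
        index correspondence with the original points is preserved.
        """
        if n == len(self.points):
            return Contour3D(self.points.copy())
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        targets = np.linspace(0.0, total, n, endpoint=False)
        idx = np.searchsorted(s, targets, side="right") - 1
        idx = np.clip(idx, 0, len(seg) - 1)
        t = (targets - s[idx]) / seg[idx]
        new = pts[idx] + t[:, None] * (pts[idx + 1] - pts[idx])
        return Contour3D(new)

    def reversed(self) -> "Contour3D":
        return Contour3D(self.points[::-1].copy())


@dataclass
class LoopImplicit:
    """Implicit function of a selection loop: signed distance to the loop prism."""

    contour: Contour3D
    direction: np.ndarray
    plane_point: np.ndarray
    _basis: tuple = field(default=None, repr=False)
    _polygon: Polygon = field(default=None, repr=False)

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        self.direction = self.direction / np.linalg.norm(self.direction)
        self.plane_point = np.asarray(self.plane_point, dtype=float).reshape(3)
        if self._basis is None:
            self._basis = plane_basis(self.direction)
        if self._polygon is None:
            self._polygon = Polygon(self.project(self.contour.points))
        if self._polygon.area <= 0:
            raise InvalidContourError("projected contour polygon has zero area")

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project world points along the loop direction to 2D plane coords."""
        u, v, _ = self._basis
        q = np.atleast_2d(np.asarray(points, dtype=float)) - self.plane_point
        return np.column_stack([q @ u, q @ v])


def build_loop_implicit(contour: Contour3D, node_normals: np.ndarray) -> LoopImplicit:
    """Build the loop implicit from a contour and per-node surface normals.

    The prism direction is the normalized mean of the node normals; the
    projection of the contour along it must be a simple polygon.
    """
    if not isinstance(contour, Contour3D):
        contour = Contour3D(np.asarray(contour))
    normals = np.asarray(node_normals, dtype=float)
    if normals.shape != contour.points.shape:
        raise ValueError("need exactly one normal per contour point")
    mean = normals.mean(axis=0)
    if np.linalg.norm(mean) < 1e-6:
        raise DegenerateDirectionError(
            "contour node normals average to zero; no prism direction"
        )
    direction = mean / np.linalg.norm(mean)
    loop = LoopImplicit(
        contour=contour, direction=direction, plane_point=contour.centroid
    )
    ring = LinearRing(loop.project(contour.points))
    if not ring.is_simple:
        raise InvalidContourError("contour self-intersects in projection")
    return loop


def implicit_values(f: LoopImplicit, points: np.ndarray) -> np.ndarray:
    """Signed distances of points to the loop prism (negative inside)."""
    coords = f.project(points)
    pts = shapely.points(coords)
    dist = shapely.distance(pts, f.polygon.exterior)
    inside = shapely.contains(f.polygon, pts)
    return np.where(inside, -dist, dist)


def implicit_value(f: LoopImplicit, p: np.ndarray) -> float:
    """Signed distance of a single point to the loop prism."""
    return float(implicit_values(f, np.asarray(p, dtype=float).reshape(1, 3))[0])


def _split_faces(vertices, faces, values, tol):
    """Split mixed-sign triangles along the zero level; keep the <= 0 side."""
    inside = values <= tol
    n_in = inside[faces].sum(axis=1)
    keep = faces[n_in == 3]
    mixed = faces[(n_in > 0) & (n_in < 3)]

    new_verts = [vertices]
    new_faces = [keep]
    offset = len(vertices)
    cache = {}

    def cut_point(i, j):
        nonlocal offset
        key = (i, j) if i < j else (j, i)
        if key in cache:
            return cache[key]
        vi, vj = values[i], values[j]
        denom = vi - vj
        t = 0.0 if abs(denom) < 1e-300 else vi / denom
        t = min(max(t, 0.0), 1.0)
        p = vertices[i] + t * (vertices[j] - vertices[i])
        new_verts.append(p[None, :])
        cache[key] = offset
        offset += 1
        return cache[key]

    extra = []
    for tri in mixed:
        ins = inside[tri]
        # rotate so the pattern is (in, out, out) or (in, in, out)
        order = np.argsort(~ins, kind="stable")
        if ins.sum() == 1:
            a = tri[order[0]]
            # preserve cyclic order of the original triangle
            idx = int(np.where(tri == a)[0][0])
            a, b, c = tri[idx], tri[(idx + 1) % 3], tri[(idx + 2) % 3]
            pab = cut_point(a, b)
            pca = cut_point(c, a)
            extra.append((a, pab, pca))
        else:
            out = tri[~ins][0]
            idx = int(np.where(tri == out)[0][0])
            c, a, b = tri[idx], tri[(idx + 1) % 3], tri[(idx + 2) % 3]
            # a, b inside; c outside; cyclic order (a, b, c)
            pbc = cut_point(b, c)
            pca = cut_point(c, a)
            extra.append((a, b, pbc))
            extra.append((a, pbc, pca))
    if extra:
        new_faces.append(np.asarray(extra, dtype=np.int64))
    verts = np.vstack(new_verts)
    faces_out = (
        np.vstack(new_faces) if new_faces else np.empty((0, 3), dtype=np.int64)
    )
    return verts, faces_out


def _weld(verts: np.ndarray, faces: np.ndarray, tol: float = 1e-4):
    """Merge vertices closer than ``tol`` (mm).

    Cut points produced by triangle splitting can land (numerically) on an
    existing vertex; left unmerged they survive in memory but collapse under
    the float32 precision of STL export, producing non-manifold edges. The
    representative of each merge group is its lowest-index member, i.e. an
    original mesh vertex whenever one is present.
    """
    keys = np.round(verts / tol).astype(np.int64)
    _, first, inv = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    rep = first[inv]
    return verts, rep[faces]


def clip_mesh(
    mesh: trimesh.Trimesh,
    f: LoopImplicit,
    tol: float = 1e-9,
    nearest_only: bool = False,
) -> trimesh.Trimesh:
    """Clip a mesh to the region where the loop implicit is <= 0.

    Triangles straddling the zero level are split by linear interpolation of
    the vertex values, so every retained vertex has value <= ``tol``.

    Because the loop implicit is an infinite prism, clipping a closed
    surface retains material on *both* sides (e.g. both caps of a sphere).
    ``nearest_only=True`` additionally keeps only the connected component
    lying furthest along the loop direction — the surface the loop was drawn
    on, mimicking the view-dependent selection of the interactive workflow.
    """
    values = implicit_values(f, mesh.vertices)
    if not np.any(values <= tol):
        raise EmptyClipError("mesh lies entirely outside the clipping loop")
    verts, faces = _split_faces(
        np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces), values, tol
    )
    if len(faces) == 0:
        raise EmptyClipError("no triangles survive the clip")
    verts, faces = _weld(verts, faces)
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    out.remove_unreferenced_vertices()
    out.update_faces(out.nondegenerate_faces(height=1e-12))
    out.remove_unreferenced_vertices()
    if len(out.faces) == 0:
        raise EmptyClipError("clip produced only degenerate triangles")
    if nearest_only:
        out = nearest_component(out, f.direction)
    return out


def nearest_component(mesh: trimesh.Trimesh, direction: np.ndarray) -> trimesh.Trimesh:
    """Connected component furthest along ``direction`` (nearest to a viewer
    looking back along it)."""
    parts = mesh.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    direction = np.asarray(direction, dtype=float)
    scores = [float(np.median(p.vertices @ direction)) for p in parts]
    return parts[int(np.argmax(scores))]
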
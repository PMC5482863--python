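"""Mid-sagittal plane estimation and mirroring of the skull mesh.

The median plane is fitted from anatomically symmetric landmark pairs:
its origin is the mean of the pair midpoints and its normal the principal
direction of the normalized pair-difference vectors (robust when pairs have
very different separations). The mirror is the reflection across that
plane, built both as the Householder closed form

    T p = p - 2 ((p - o) . n) n

and as the five-factor product

    T = A  B  M  B^-1  A^-1

where, reading the factors right-to-left in application order, ``A^-1``
translates the plane origin to the world origin, ``B^-1`` rotates the plane
normal onto +x, ``M = diag(-1, 1, 1)`` reflects across the plane x = 0, and
the remaining factors undo the change of frame.  The product is asserted to
match the closed form to 1e-9.

A historical variant replaces the reflection M with a proper 180° rotation
about the y axis; that composite is a rotation (det +1), not a mirror, and
is exposed only via ``mirror_transform(..., rotation_variant=True)`` for
reproduction studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import DegeneratePairError

__all__ = [
    "LandmarkPairs",
    "Plane",
    "MirrorTransform",
    "fit_median_plane",
    "mirror_transform",
    "mirror_mesh",
]

_UNIT_TOL = 1e-9


@dataclass
class LandmarkPairs:
    """Paired anatomically symmetric landmarks, shape (n, 2, 3), world mm."""

    pairs: np.ndarray

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=float)
        if self.pairs.ndim != 3 or self.pairs.shape[1:] != (2, 3) or len(self.pairs) < 1:
            raise ValueError("pairs must have shape (n, 2, 3) with n >= 1")
        if not np.isfinite(self.pairs).all():
            raise DegeneratePairError("landmark coordinates must be finite")
        sep = np.linalg.norm(self.pairs[:, 1] - self.pairs[:, 0], axis=1)
        if np.any(sep < 1e-12):
            bad = int(np.argmin(sep))
            raise DegeneratePairError(f"pair {bad} has zero separation")

    def __len__(self):
        return len(self.pairs)


@dataclass
class Plane:
    """A plane given by a point on it and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if n < 1e-12:
            raise ValueError("plane normal must be nonzero")
        if abs(n - 1.0) > _UNIT_TOL:
            self.normal = self.normal / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.origin) @ self.normal


@dataclass
class MirrorTransform:
    """4x4 homogeneous reflection across a plane, with its factor decomposition.

    ``matrix`` is the composite; ``factors`` are the five homogeneous
    matrices whose product (left to right) equals ``matrix``.
    """

    matrix: np.ndarray
    factors: tuple

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        assert self.matrix.shape == (4, 4)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) or (3,) array of points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out


def fit_median_plane(pairs: LandmarkPairs) -> Plane:
    """Fit the median plane from symmetric landmark pairs.

    Origin is the mean of pair midpoints. The normal is the dominant
    principal direction (largest singular value) of the unit pair-difference
    vectors; for a single pair this is its perpendicular bisector. The sign
    is chosen to point from the first pair's first point toward its second.
    """
    if not isinstance(pairs, LandmarkPairs):
        pairs = LandmarkPairs(np.asarray(pairs))
    p, q = pairs.pairs[:, 0], pairs.pairs[:, 1]
    origin = 0.5 * (p + q).mean(axis=0)
    diffs = q - p
    units = diffs / np.linalg.norm(diffs, axis=1, keepdims=True)
    if len(units) == 1:
        normal = units[0]
    else:
        # dominant right singular vector of the unit differences
        _, _, vt = np.linalg.svd(units, full_matrices=False)
        normal = vt[0]
    if normal @ units[0] < 0:
        normal = -normal
    return Plane(origin=origin, normal=normal)


def _translation(t: np.ndarray) -> np.ndarray:
    m = np.eye(4)
    m[:3, 3] = t
    return m


def _rotation_to_x(normal: np.ndarray) -> np.ndarray:
    """4x4 rotation taking ``normal`` onto +x (minimal-angle, axis n x x̂)."""
    n = normal / np.linalg.norm(normal)
    x = np.array([1.0, 0.0, 0.0])
    axis = np.cross(n, x)
    s = np.linalg.norm(axis)
    c = float(n @ x)
    m = np.eye(4)
    if s < 1e-12:
        if c > 0:  # already +x
            return m
        # antiparallel: fixed 180° rotation about y (tie-break)
        m[:3, :3] = np.diag([-1.0, 1.0, -1.0])
        return m
    axis = axis / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    m[:3, :3] = np.eye(3) + s * k + (1 - c) * (k @ k)
    return m


def mirror_transform(plane: Plane, rotation_variant: bool = False) -> MirrorTransform:
    """Reflection across ``plane`` as composite and five-factor decomposition.

    With ``rotation_variant=True`` the middle factor is a proper 180°
    rotation about y instead of the x = 0 reflection; the composite is then
    a rotation about the in-plane y-like axis, not a mirror, and is provided
    only for comparison with implementations that composed it that way.
    """
    n = np.asarray(plane.normal, dtype=float)
    norm = np.linalg.norm(n)
    if abs(norm - 1.0) > _UNIT_TOL:
        warnings.warn("plane normal was not unit length; normalizing", stacklevel=2)
        n = n / norm
    o = np.asarray(plane.origin, dtype=float)

    rot = _rotation_to_x(n)  # B^-1: plane normal -> +x
    mid = np.eye(4)
    if rotation_variant:
        mid[:3, :3] = np.diag([-1.0, 1.0, -1.0])  # 180° about y
    else:
        mid[:3, :3] = np.diag([-1.0, 1.0, 1.0])  # reflect across x = 0

    factors = (
        _translation(o),  # A
        rot.T,            # B  (inverse rotation: +x -> plane normal)
        mid,              # M
        rot,              # B^-1
        _translation(-o), # A^-1
    )
    matrix = np.linalg.multi_dot(factors)
    if not rotation_variant:
        # must equal the Householder closed form
        closed = np.eye(4)
        closed[:3, :3] = np.eye(3) - 2.0 * np.outer(n, n)
        closed[:3, 3] = 2.0 * (o @ n) * n
        assert np.allclose(matrix, closed, atol=1e-9)
    return MirrorTransform(matrix=matrix, factors=factors)


def mirror_mesh(mesh: trimesh.Trimesh, t: MirrorTransform) -> trimesh.Trimesh:
    """Mirror a mesh, reversing face winding to preserve outward orientation.

    The reflection is orientation-reversing, so faces are rewound; the
    signed volume of a closed mesh is therefore preserved.
    """
    verts = t.apply(mesh.vertices)
    faces = np.asarray(mesh.faces)[:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)
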
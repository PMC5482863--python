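"""Synthetic skull-like test cases with analytic ground truth.

A two-layer ellipsoidal shell stands in for the cranial vault: every oracle
(shell volume, surface area, symmetry plane) is then analytic, which a
scanned skull could never offer. The shell is exactly symmetric about the
x = 0 plane (the voxel grid is built so that plane is a grid symmetry
plane), landmark pairs are placed at exactly mirrored analytic surface
points, and a spherical "defect" is punched strictly on one side of the
midplane so the mirrored intact side provides the geometric ground truth.

What this emulates: the gross geometry of a segmented skull with a single
penetrating defect. What it does not: CT noise, beam hardening, sutures,
variable bone density, or real anatomical asymmetry (a mild asymmetric
surface bump is available via ``bump_amplitude`` to exercise the
inexact-symmetry path).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import trimesh

from . import io as spio
from .clip import Contour3D, plane_basis
from .errors import GeometryError, InvalidDefectError
from .implant import boundary_loops
from .symmetry import LandmarkPairs
from .volume import (
    ScalarVolume,
    extract_isosurface,
    region_grow,
    threshold_segment,
)

__all__ = ["SyntheticCase", "make_skull", "punch_defect", "write_case"]

SHELL_INTENSITY = 1000.0
DEFAULT_RADII = (80.0, 100.0, 70.0)
DEFAULT_WALL = 6.0
DEFAULT_SPACING = 1.0
DEFAULT_DEFECT_RADIUS = 25.0


@dataclass
class SyntheticCase:
    """A generated skull case with every ground-truth object kept alongside."""

    volume: ScalarVolume
    skull_mesh: trimesh.Trimesh
    landmarks: LandmarkPairs
    outer_radii: np.ndarray
    wall: float
    seed: int
    seed_voxel: tuple
    threshold: float
    defect_center: np.ndarray | None = None
    defect_radius: float = 0.0
    rim_contour: Contour3D | None = None
    truth_patch: trimesh.Trimesh | None = None
    intact_mesh: trimesh.Trimesh | None = None

    @property
    def spacing(self) -> np.ndarray:
        return self.volume.spacing

    def fit_contour(self, dilation: float = 1.2) -> Contour3D:
        """Rim contour dilated in its own plane — the selection contour a
        user would draw comfortably outside the defect edge."""
        if self.rim_contour is None:
            raise GeometryError("case has no defect; punch one first")
        pts = self.rim_contour.points
        center = pts.mean(axis=0)
        normal = _outward_normals(pts, self.outer_radii)
        u, v, w = plane_basis(normal.mean(axis=0))
        q = pts - center
        scaled = (
            center
            + dilation * (q @ u)[:, None] * u
            + dilation * (q @ v)[:, None] * v
            + (q @ w)[:, None] * w
        )
        return Contour3D(scaled)


def _rho(points: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Normalized ellipsoidal radius: 1 on the ellipsoid surface."""
    q = np.atleast_2d(points) / radii
    return np.sqrt(np.einsum("ij,ij->i", q, q))


def _outward_normals(points: np.ndarray, radii: np.ndarray) -> np.ndarray:
    grad = 2.0 * np.atleast_2d(points) / np.asarray(radii) ** 2
    return grad / np.linalg.norm(grad, axis=1, keepdims=True)


def _ellipsoid_point(radii, theta, phi):
    return np.array(
        [
            radii[0] * np.sin(phi) * np.cos(theta),
            radii[1] * np.sin(phi) * np.sin(theta),
            radii[2] * np.cos(phi),
        ]
    )


def make_skull(
    outer_radii=DEFAULT_RADII,
    wall: float = DEFAULT_WALL,
    spacing: float = DEFAULT_SPACING,
    seed: int = 0,
    bump_amplitude: float = 0.0,
    margin_voxels: int = 4,
) -> SyntheticCase:
    """Ellipsoidal two-layer shell volume + mesh + exact landmark pairs.

    Shell voxels have intensity 1000, background 0. The voxel grid is
    centered so x = 0 is an exact grid symmetry plane. ``bump_amplitude``
    (mm, <= 1 recommended) adds a smooth asymmetric bump on the +x side.
    """
    radii = np.asarray(outer_radii, dtype=float)
    if wall >= radii.min():
        raise GeometryError(f"wall {wall} mm must be thinner than min radius {radii.min()}")
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    inner = radii - wall

    half = radii + margin_voxels * spacing
    nhalf = np.ceil(half / spacing).astype(int)
    counts = 2 * nhalf + 1  # odd: x = 0 is a voxel plane
    origin = -nhalf * spacing

    ax = [origin[k] + spacing * np.arange(counts[k]) for k in range(3)]
    x = ax[0][:, None, None]
    y = ax[1][None, :, None]
    z = ax[2][None, None, :]
    rho_out2 = (x / radii[0]) ** 2 + (y / radii[1]) ** 2 + (z / radii[2]) ** 2
    rho_in2 = (x / inner[0]) ** 2 + (y / inner[1]) ** 2 + (z / inner[2]) ** 2
    shell = (rho_out2 <= 1.0) & (rho_in2 >= 1.0)
    if bump_amplitude > 0.0:
        rng = np.random.default_rng(seed)
        cy = rng.uniform(-0.3, 0.3) * radii[1]
        cz = rng.uniform(-0.3, 0.3) * radii[2]
        sigma = 0.25 * radii.min()
        bump = (bump_amplitude / radii.min()) * np.exp(
            -((y - cy) ** 2 + (z - cz) ** 2) / sigma**2
        )
        shell = ((np.sqrt(rho_out2) - np.where(x > 0, bump, 0.0)) <= 1.0) & (
            rho_in2 >= 1.0
        )
    data = np.where(shell, SHELL_INTENSITY, 0.0).astype(np.float32)
    vol = ScalarVolume(data=data, spacing=np.full(3, float(spacing)), origin=origin)

    # landmark pairs: exactly mirrored analytic points on the outer surface
    angles = [
        (0.35, 1.2),
        (0.9, 0.7),
        (1.4, 1.5),
        (0.6, 2.0),
        (1.1, 1.0),
    ]
    pairs = []
    for theta, phi in angles:
        p = _ellipsoid_point(radii, theta, phi)
        q = p * np.array([-1.0, 1.0, 1.0])
        pairs.append([q, p])  # left (x<0...) first; p has x>0
    landmarks = LandmarkPairs(np.asarray(pairs))

    threshold = SHELL_INTENSITY / 2.0
    seed_world = np.array([0.0, radii[1] - wall / 2.0, 0.0])
    seed_voxel = tuple(int(v) for v in np.round((seed_world - origin) / spacing))
    mask = region_grow(threshold_segment(vol, threshold), seed_voxel)
    mesh = extract_isosurface(mask)

    return SyntheticCase(
        volume=vol,
        skull_mesh=mesh,
        landmarks=landmarks,
        outer_radii=radii,
        wall=float(wall),
        seed=int(seed),
        seed_voxel=seed_voxel,
        threshold=threshold,
    )


def punch_defect(
    case: SyntheticCase,
    center=None,
    radius: float = DEFAULT_DEFECT_RADIUS,
) -> SyntheticCase:
    """Punch a spherical defect into the shell, recording the ground truth.

    ``center`` defaults to a point on the outer surface on the -x side.
    The defect must stay strictly on one side of the midplane (it must not
    cross x = 0, which would corrupt the mirroring ground truth). The truth
    patch is the *intact* outer-sheet surface inside the punch sphere; the
    rim contour is its ordered boundary.
    """
    radii = case.outer_radii
    if center is None:
        center = _ellipsoid_point(radii, np.pi - 0.5, 1.1)  # -x hemisphere
    center = np.asarray(center, dtype=float)
    if radius < 0:
        raise InvalidDefectError("defect radius must be >= 0")
    if radius == 0:
        return replace(case)
    if abs(center[0]) <= radius:
        raise InvalidDefectError(
            f"defect at x={center[0]:.1f} with radius {radius} crosses the midplane"
        )
    rho_c = _rho(center[None], radii)[0]
    if not (0.8 <= rho_c <= 1.2):
        raise InvalidDefectError("defect center must lie on the shell surface")

    vol = case.volume
    counts = vol.shape
    ax = [vol.origin[k] + vol.spacing[k] * np.arange(counts[k]) for k in range(3)]
    d2 = (
        (ax[0][:, None, None] - center[0]) ** 2
        + (ax[1][None, :, None] - center[1]) ** 2
        + (ax[2][None, None, :] - center[2]) ** 2
    )
    data = np.where(d2 <= radius**2, 0.0, vol.data).astype(np.float32)
    new_vol = ScalarVolume(data=data, spacing=vol.spacing, origin=vol.origin)

    mask = region_grow(
        threshold_segment(new_vol, case.threshold), case.seed_voxel
    )
    new_mesh = extract_isosurface(mask)

    intact = case.skull_mesh
    truth_patch = _outer_sheet_patch(intact, radii, case.wall, center, radius)
    rim = _ordered_rim(truth_patch)

    return replace(
        case,
        volume=new_vol,
        skull_mesh=new_mesh,
        defect_center=center,
        defect_radius=float(radius),
        truth_patch=truth_patch,
        rim_contour=rim,
        intact_mesh=intact,
    )


def _outer_sheet_patch(mesh, radii, wall, center, radius) -> trimesh.Trimesh:
    """Faces of the intact mesh on the outer sheet inside the punch sphere."""
    centroids = mesh.triangles_center
    rho = _rho(centroids, radii)
    rho_inner_max = ((radii - wall) / radii).max()
    on_outer = rho > 0.5 * (1.0 + rho_inner_max)
    in_sphere = np.linalg.norm(centroids - center, axis=1) < radius
    idx = np.where(on_outer & in_sphere)[0]
    if len(idx) == 0:
        raise InvalidDefectError("punch sphere does not intersect the outer sheet")
    patch = mesh.submesh([idx], append=True)
    patch.remove_unreferenced_vertices()
    parts = patch.split(only_watertight=False)
    if len(parts) > 1:
        patch = parts[int(np.argmax([p.area for p in parts]))]
    return patch


def _ordered_rim(patch: trimesh.Trimesh) -> Contour3D:
    loops = boundary_loops(patch)
    loop = max(loops, key=len)
    return Contour3D(np.asarray(patch.vertices)[loop])


def write_case(case: SyntheticCase, out_dir, fit_dilation: float = 1.2) -> Path:
    """Write a case directory in exactly the formats the CLI consumes.

    Contents: volume container (volume.json/.bin), landmarks.txt,
    contour_fit.txt and contour_edge.txt (for a punched case), case.json
    with the segmentation parameters, plus STL ground truth meshes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.save_volume(case.volume, out / "volume")
    spio.save_landmarks(case.landmarks, out / "landmarks.txt")
    meta = {
        "seed": case.seed,
        "threshold_lo": case.threshold,
        "seed_voxel": list(case.seed_voxel),
        "outer_radii_mm": case.outer_radii.tolist(),
        "wall_mm": case.wall,
        "spacing_mm": case.spacing.tolist(),
    }
    spio.save_mesh(case.skull_mesh, out / "skull.stl")
    if case.rim_contour is not None:
        spio.save_contour(case.fit_contour(fit_dilation), out / "contour_fit.txt")
        spio.save_contour(case.rim_contour, out / "contour_edge.txt")
        spio.save_mesh(case.truth_patch, out / "truth_patch.stl")
        meta["defect_center_mm"] = case.defect_center.tolist()
        meta["defect_radius_mm"] = case.defect_radius
    (out / "case.json").write_text(json.dumps(meta, indent=2))
    return out
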
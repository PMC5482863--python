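"""File formats: the minimal volume container, landmark/contour text files,
flat key=value configs, and STL meshes (via trimesh).

Volume container: ``<name>.json`` sidecar (shape, spacing, origin, dtype)
next to ``<name>.bin`` holding the raw array, C-order, little-endian.
Landmark files hold one pair per line as six whitespace-separated mm
coordinates; contour files one point (three coordinates) per line; ``#``
starts a comment in both.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .clip import Contour3D
from .symmetry import LandmarkPairs
from .volume import ScalarVolume

__all__ = [
    "save_volume",
    "load_volume",
    "load_nifti",
    "save_landmarks",
    "load_landmarks",
    "save_contour",
    "load_contour",
    "load_mesh",
    "save_mesh",
    "load_config_file",
]


def save_volume(vol: ScalarVolume, prefix) -> None:
    """Write ``<prefix>.json`` + ``<prefix>.bin`` (little-endian, C-order)."""
    prefix = Path(prefix)
    data = np.ascontiguousarray(vol.data.astype("<f4"))
    meta = {
        "shape": list(vol.data.shape),
        "spacing_mm": vol.spacing.tolist(),
        "origin_mm": vol.origin.tolist(),
        "dtype": "float32",
        "byte_order": "little-endian",
        "order": "C",
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    data.tofile(prefix.with_suffix(".bin"))


def load_volume(prefix) -> ScalarVolume:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".bin"), dtype="<f4").reshape(meta["shape"])
    return ScalarVolume(
        data=data, spacing=np.array(meta["spacing_mm"]), origin=np.array(meta["origin_mm"])
    )


def load_nifti(path) -> ScalarVolume:
    """Import a NIfTI volume (spacing/origin from the affine; no axis flips)."""
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    return ScalarVolume(
        data=np.asarray(img.dataobj), spacing=spacing, origin=affine[:3, 3]
    )


def _read_table(path, ncols: int) -> np.ndarray:
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != ncols:
            raise ValueError(
                f"{path}:{lineno}: expected {ncols} values, found {len(parts)}"
            )
        rows.append([float(x) for x in parts])
    return np.asarray(rows, dtype=float)


def save_landmarks(pairs: LandmarkPairs, path) -> None:
    arr = pairs.pairs.reshape(len(pairs), 6)
    lines = ["# x_left y_left z_left x_right y_right z_right (mm)"]
    lines += [" ".join(f"{v:.9g}" for v in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def load_landmarks(path) -> LandmarkPairs:
    arr = _read_table(path, 6)
    if len(arr) == 0:
        raise ValueError(f"{path}: no landmark pairs found")
    return LandmarkPairs(arr.reshape(-1, 2, 3))


def save_contour(contour: Contour3D, path) -> None:
    lines = ["# x y z (mm), ordered closed contour"]
    lines += [" ".join(f"{v:.9g}" for v in row) for row in contour.points]
    Path(path).write_text("\n".join(lines) + "\n")


def load_contour(path) -> Contour3D:
    arr = _read_table(path, 3)
    return Contour3D(arr)


def load_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh")
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Binary STL, mm units."""
    mesh.export(str(path), file_type="stl")


def load_config_file(path) -> dict:
    """Flat ``key = value`` text config; values parsed as JSON when possible."""
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        value = value.strip()
        try:
            out[key.strip()] = json.loads(value)
        except json.JSONDecodeError:
            out[key.strip()] = value
    return out
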
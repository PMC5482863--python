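import numpy as np
import pytest
import trimesh

from skullpatch.pipeline import PipelineConfig, run_pipeline
from skullpatch.synthetic import make_skull, punch_defect, write_case


@pytest.fixture(scope="session")
def default_case():
    """The default synthetic skull: 80/100/70 mm ellipsoid, 6 mm wall,
    1 mm voxels, 25 mm defect punched on the -x side."""
    return punch_defect(make_skull(seed=0))


@pytest.fixture(scope="session")
def default_case_dir(default_case, tmp_path_factory):
    out = tmp_path_factory.mktemp("default_case")
    write_case(default_case, out)
    return out


@pytest.fixture(scope="session")
def small_case_dir(tmp_path_factory):
    """A scaled-down case for fast CLI / IO round-trip checks."""
    case = punch_defect(
        make_skull(outer_radii=(40.0, 50.0, 35.0), wall=6.0, spacing=2.0, seed=0),
        radius=14.0,
    )
    out = tmp_path_factory.mktemp("small_case")
    write_case(case, out)
    return out


@pytest.fixture(scope="session")
def pipeline_result(default_case_dir, tmp_path_factory):
    """One full pipeline run on the default case, shared across tests."""
    import time

    out = tmp_path_factory.mktemp("pipeline_out")
    t0 = time.perf_counter()
    report = run_pipeline(PipelineConfig(), default_case_dir, out)
    elapsed = time.perf_counter() - t0
    return {"out_dir": out, "report": report, "seconds": elapsed}


def icosphere(radius=20.0, subdivisions=3):
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)


def spherical_cap_patch(radius=20.0, cap_angle_deg=30.0, subdivisions=4):
    """Open spherical-cap mesh around +z (faces fully inside the cone)."""
    sphere = icosphere(radius, subdivisions)
    cos_lim = np.cos(np.radians(cap_angle_deg))
    keep = np.where(
        (sphere.vertices[sphere.faces][:, :, 2] > radius * cos_lim).all(axis=1)
    )[0]
    patch = sphere.submesh([keep], append=True)
    patch.remove_unreferenced_vertices()
    return patch


def star_loop(rng, n_points, base_radius=5.0, wobble=0.0):
    """Random simple polygon, star-shaped about the origin.

    Angles are jittered from a regular spacing (keeping every angular gap
    well below pi, which guarantees simplicity); ``wobble`` > 0 perturbs the
    radii for a non-convex star shape, 0 gives a convex inscribed polygon.
    """
    ang = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    ang = ang + rng.uniform(0.05, 0.9, n_points) * (2 * np.pi / n_points)
    radius = base_radius + (
        rng.uniform(-wobble, wobble, n_points) if wobble else np.zeros(n_points)
    )
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n_points)]
    )


def ring_contour(radius, polar_deg, n=64, sphere_radius=None):
    """Circular contour at a given polar angle on a sphere (or a flat circle)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    if sphere_radius is None:
        return np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)])
    pol = np.radians(polar_deg)
    r = sphere_radius
    return np.column_stack(
        [
            r * np.sin(pol) * np.cos(t),
            r * np.sin(pol) * np.sin(t),
            np.full(n, r * np.cos(pol)),
        ]
    )
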
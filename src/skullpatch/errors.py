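"""Exception hierarchy.

Every stage raises a subclass of :class:`SkullpatchError` so the pipeline
driver can attach the stage name and a remediation hint before the CLI
turns it into a nonzero exit status.
"""


class SkullpatchError(Exception):
    """Base class for all errors raised by this package."""


class InvalidRangeError(SkullpatchError):
    """Threshold window with lo > hi."""


class SeedError(SkullpatchError):
    """Region-growing seed outside the grid or on a background voxel."""


class EmptySurfaceError(SkullpatchError):
    """Isosurface requested from an all-true or all-false mask."""


class DegeneratePairError(SkullpatchError):
    """Landmark pair with (near-)zero separation or non-finite coordinates."""


class DegenerateDirectionError(SkullpatchError):
    """Contour node normals average to (near) zero."""


class InvalidContourError(SkullpatchError):
    """Contour is self-intersecting, collinear, or otherwise unusable."""


class EmptyClipError(SkullpatchError):
    """No part of the mesh lies inside the clipping loop."""


class InsufficientPointsError(SkullpatchError):
    """Fewer than three points survive projection dedup."""


class DegenerateTriangulationError(SkullpatchError):
    """All projected points collinear; no 2D triangulation exists."""


class SelfIntersectionError(SkullpatchError):
    """Offsetting inverted one or more faces (thickness too large)."""

    def __init__(self, message, face_indices=None):
        super().__init__(message)
        self.face_indices = face_indices


class ZeroAreaError(SkullpatchError):
    """Ruled wall between coincident loops would have zero area."""


class TopologyError(SkullpatchError):
    """Surface topology unsuitable for solidification (e.g. >1 boundary loop)."""


class GeometryError(SkullpatchError):
    """Invalid geometric parameters (e.g. wall thicker than the shell radius)."""


class InvalidDefectError(SkullpatchError):
    """Synthetic defect would cross the midplane and corrupt the ground truth."""


class VoxelizationError(SkullpatchError):
    """Voxel overlap requested for a non-watertight mesh."""


class EmptyInputError(SkullpatchError):
    """Empty mesh passed where geometry is required."""


class PipelineError(SkullpatchError):
    """A pipeline stage failed; carries the stage name and a hint."""

    def __init__(self, stage, message, hint=""):
        self.stage = stage
        self.hint = hint
        super().__init__(f"[{stage}] {message}" + (f" (hint: {hint})" if hint else ""))
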
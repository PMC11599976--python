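"""Exception hierarchy for the femur3d pipeline.

Every stage of the measurement pipeline raises a distinct subclass of
:class:`Femur3DError`, so callers (and the CLI) can map failures to the
stage that produced them.
"""


class Femur3DError(Exception):
    """Base class for all femur3d errors."""


class MeshFormatError(Femur3DError):
    """The STL file is unreadable, truncated, or otherwise malformed."""


class EmptyMeshError(Femur3DError):
    """A mesh with no vertices or faces was supplied."""


class DegenerateGeometryError(Femur3DError):
    """Input geometry does not determine the requested primitive
    (coplanar points for a sphere, identical points for a line, ...)."""


class SeedError(Femur3DError):
    """The head seed point is too far from the mesh surface."""


class FitFailureError(Femur3DError):
    """An iterative fit collapsed or failed to produce a usable result."""


class AxisFailureError(Femur3DError):
    """Too few usable diaphyseal sections to fit the anatomical axis."""


class NeckFailureError(Femur3DError):
    """No femoral-neck section could be found at any admissible radius."""


class CondyleFailureError(Femur3DError):
    """Condylar sphere support collapsed below the usable minimum."""


class JointLineError(Femur3DError):
    """The common-tangent construction for the joint line did not converge."""


class FrameError(Femur3DError):
    """Anatomical axis and joint line are too close to parallel."""


class StageError(Femur3DError):
    """Wraps a pipeline failure with the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


class RecordParseError(Femur3DError):
    """A clinical fixture row could not be parsed; carries the case id."""

    def __init__(self, case_id, message: str):
        self.case_id = case_id
        super().__init__(f"case {case_id}: {message}")


class IncompleteRecordError(Femur3DError):
    """An outcome classification was requested on a record with missing fields."""


class SpecError(Femur3DError):
    """A synthetic-femur parameter combination is invalid or self-intersecting."""
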
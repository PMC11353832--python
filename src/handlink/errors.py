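"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`HandlinkError`
so callers (and the CLI) can distinguish validation problems from geometry
problems with a single ``except``.
"""


class HandlinkError(Exception):
    """Base class for all handlink errors."""


class ValidationError(HandlinkError):
    """Malformed inputs: bad schemas, missing files, out-of-range parameters."""


class GeometryError(HandlinkError):
    """A geometric operation could not be carried out on the given data."""


class MeshFormatError(ValidationError):
    """An STL file could not be parsed; the message names the byte offset."""


class AmbiguousAxisError(GeometryError):
    """Inertia tensor nearly degenerate: no unique long axis exists."""


class UndefinedProjectionError(GeometryError):
    """A vector is (near-)parallel to the projection plane normal."""


class EmptyFragmentError(GeometryError):
    """A cutting plane does not intersect the mesh."""


class UnsupportedMeshError(GeometryError):
    """Operation requires a watertight mesh and the input is not."""


class DegenerateFitError(GeometryError):
    """Circle fit on collinear or otherwise degenerate points."""


class SelectionError(GeometryError):
    """Condyle point selection produced too few points."""


class UnstableAxisError(GeometryError):
    """Fitted condylar circle centers are too close to define an axis."""


class InvalidAnatomyError(GeometryError):
    """Axes in an anatomically impossible configuration (e.g. rotation axis
    parallel to the long axis)."""


class PlanningError(ValidationError):
    """Osteotomy plan parameters out of range or plane misses the bone."""


class StructuralError(ValidationError):
    """Kinematic chain or hand model wiring is inconsistent."""


class LayoutError(GeometryError):
    """Generated digits overlap at zero pose."""


class GenerationError(GeometryError):
    """Synthetic bone generation produced invalid geometry."""


class ParameterError(ValidationError):
    """Synthetic generator parameters out of their documented range."""


class DependencyError(ValidationError):
    """A workflow stage was run before the stage that produces its inputs."""
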
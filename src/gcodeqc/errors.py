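"""Exception hierarchy for the G-code fidelity pipeline.

Every stage raises a subclass of :class:`GCodeQCError` so that the CLI can
report which stage failed and with what diagnostic counts.
"""


class GCodeQCError(Exception):
    """Base class for all pipeline errors."""


class DialectError(GCodeQCError):
    """G-code uses an unsupported dialect feature (e.g. G2/G3 arc moves)."""


class UnitError(GCodeQCError):
    """G-code switches to inch units (G20); only millimetres are supported."""


class MalformedSegmentError(GCodeQCError):
    """An extrusion move is not planar (start and end Z differ)."""


class EmptyCloudError(GCodeQCError):
    """An operation received or produced a point cloud with no points."""


class StageError(GCodeQCError):
    """A staged point cloud was fed to the wrong correction stage."""


class ResolutionError(GCodeQCError):
    """The requested voxel size would exceed the configured cell budget."""


class SplitError(GCodeQCError):
    """The scene does not contain exactly two disconnected components."""


class CalibrationNotFoundError(GCodeQCError):
    """No connected component matches the calibration-object dimensions."""


class RegistrationError(GCodeQCError):
    """ICP diverged or the initial alignment was outside the basin."""


class NonWatertightError(GCodeQCError):
    """A mesh operation requiring a closed 2-manifold received an open mesh."""
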
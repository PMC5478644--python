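"""Exception hierarchy for deamscan.

Every error raised by the library derives from :class:`DeamscanError`, so
callers (and the CLI) can separate analysis failures from programming errors.
"""


class DeamscanError(Exception):
    """Base class for all deamscan errors."""


class PdbParseError(DeamscanError):
    """A PDB record could not be parsed; the message names the line number."""


class EmptyStructureError(PdbParseError):
    """A PDB file contained no ATOM/HETATM records."""


class TrajectoryInconsistencyError(DeamscanError):
    """Models of a multi-model PDB disagree in atom count or ordering."""


class SelectionError(DeamscanError):
    """An atom selection did not resolve as required."""


class PairingError(DeamscanError):
    """Atom lists for superposition could not be matched one-to-one."""


class UnderdeterminedError(DeamscanError):
    """Fewer than three matched atoms; a rigid superposition is undefined."""


class GeometryError(DeamscanError):
    """Degenerate or incomplete geometry (collinear ring, missing atom...)."""


class ConstructionError(DeamscanError):
    """A synthetic fixture could not be built from mutually consistent plants."""


class InsufficientFramesError(DeamscanError):
    """Too few trajectory frames for the requested analysis."""


class UndefinedLaneError(DeamscanError):
    """A gel lane carries no intensity in either of the two quantified bands."""


class UndefinedCorrelationError(DeamscanError):
    """Pearson correlation is undefined (zero variance)."""


class DesignError(DeamscanError):
    """An oligo design constraint was violated (e.g. a C inside a flank)."""


class InputError(DeamscanError):
    """An input does not match what the analysis was configured for."""
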
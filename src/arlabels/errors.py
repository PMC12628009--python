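"""Exception hierarchy shared across the package.

Every failure mode named in a module contract maps to a distinct class so
callers (and the CLI) can react to specific conditions without string
matching.
"""


class ARLabelsError(Exception):
    """Base class for all package-specific errors."""


# --- geometry ---------------------------------------------------------------

class DegenerateTriangleError(ARLabelsError):
    """Triangle with (near-)zero area where a proper triangle is required."""


class EmptyMeshError(ARLabelsError):
    """Operation requires a mesh with at least one face."""


class NotWatertightError(ARLabelsError):
    """Containment queries require a closed, consistently oriented mesh."""


class OutOfRangeError(ARLabelsError):
    """Query parameter outside its documented domain (e.g. interpolation time)."""


# --- calibration ------------------------------------------------------------

class ConditioningError(ARLabelsError):
    """Calibration system is rank deficient or too ill-conditioned to solve."""

    def __init__(self, message: str, condition_number: float = float("inf")):
        super().__init__(message)
        self.condition_number = condition_number


class UnderdeterminedError(ARLabelsError):
    """Not enough independent observations to determine the unknowns."""


class DegenerateConfigurationError(ARLabelsError):
    """Point configuration (collinear, coincident) unusable for registration."""


# --- session I/O ------------------------------------------------------------

class SessionError(ARLabelsError):
    """Base class for session-format violations."""


class MissingFileError(SessionError):
    pass


class UnknownFrameError(SessionError):
    pass


class DuplicateLabelError(SessionError):
    pass


class DuplicateEdgeError(SessionError):
    pass


class UnsortedStreamError(SessionError):
    pass


class ManifestError(SessionError):
    """Structurally invalid manifest content."""


# --- replay -----------------------------------------------------------------

class DisconnectedFramesError(ARLabelsError):
    """No path between two frames in the session frame graph."""


class EmptyClockError(ARLabelsError):
    pass


# --- events -----------------------------------------------------------------

class ConfigurationError(ARLabelsError):
    """Invalid rule configuration (checked at load time, never mid-run)."""


# --- synthetic sessions -----------------------------------------------------

class ScriptError(ARLabelsError):
    """Contradictory synthetic-session script (e.g. contact with an unknown
    structure, overlapping contact segments)."""
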
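"""Exception hierarchy shared across the package."""


class MDEnsembleError(Exception):
    """Base class for all package errors."""


class StructureFormatError(MDEnsembleError):
    """A structure file could not be parsed."""


class EmptyModelError(MDEnsembleError):
    """A structure file parsed but contained no atoms."""


class SelectionError(MDEnsembleError):
    """A selection expression is invalid or references unknown tokens."""


class AtomCountMismatchError(MDEnsembleError):
    """Trajectory and topology disagree on atom count."""


class TrajectoryTruncationError(MDEnsembleError):
    """A trajectory file ended mid-frame."""

    def __init__(self, message: str, last_complete_frame: int):
        super().__init__(message)
        self.last_complete_frame = last_complete_frame


class DegenerateGeometryError(MDEnsembleError):
    """Too few or collinear atoms for a rigid-body fit."""


class NotPositiveSemiDefiniteError(MDEnsembleError):
    """A target correlation matrix is not positive semi-definite."""


class PlacementError(MDEnsembleError):
    """Particle placement failed after bounded retries."""


class ConfigError(MDEnsembleError):
    """Pipeline configuration is invalid; message itemizes problems."""
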
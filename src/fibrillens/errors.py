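"""Exception hierarchy.

Every error raised by the library derives from :class:`FibrillensError`
so callers can catch pipeline failures with a single except clause while
still discriminating the stage that failed.
"""


class FibrillensError(Exception):
    """Base class for all fibrillens errors."""


class ValidationError(FibrillensError, ValueError):
    """Invalid argument or contract violation."""


class ReadError(FibrillensError, IOError):
    """A record or label file could not be read."""


class DegenerateSignalError(FibrillensError):
    """Signal is constant / has no power where a ratio is required."""


class FilteringError(FibrillensError):
    """Input too short (or otherwise unusable) for the prefilter."""


class DelineationError(FibrillensError):
    """A median-beat landmark could not be located.

    The missing landmark name is carried in :attr:`landmark`.
    """

    def __init__(self, message: str, landmark: str | None = None):
        super().__init__(message)
        self.landmark = landmark


class EstimationError(FibrillensError):
    """Spectral estimation failed (e.g. residual too short)."""


class ConstructionError(FibrillensError):
    """Dominant-waveform (SBMM) construction failed."""


class TrainingError(FibrillensError):
    """Network training produced a non-finite loss or diverged."""
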
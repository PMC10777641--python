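"""Exception hierarchy shared across the package."""


class ECAPLoopError(Exception):
    """Base class for all package-specific errors."""


class WindowError(ECAPLoopError):
    """A time window is too short, outside the sweep, or incompatible with
    the waveform support (e.g. conduction delay pushes N1 past the sweep end)."""


class NotDetectedError(ECAPLoopError):
    """No detectable ECAP was found anywhere in a current sweep."""


class DegenerateRecruitmentError(ECAPLoopError):
    """A recruitment fit produced a non-positive slope."""


class UndefinedRatioError(ECAPLoopError):
    """MT:ECAPT ratio requested with a non-positive ECAP threshold."""


class InsufficientDataError(ECAPLoopError):
    """Fewer usable observations than the estimator requires."""


class PropagationDirectionError(ECAPLoopError):
    """Latencies do not increase with distance from the stimulation contact."""


class DegenerateSessionError(ECAPLoopError):
    """A session summary was requested but every record was excluded."""


class DesignError(ECAPLoopError):
    """A statistical design is unusable (empty cells, too few subjects per cell)."""


class ConfigurationError(ECAPLoopError):
    """Invalid generator or controller configuration."""


class InconsistentThresholdWarning(UserWarning):
    """Extrapolated ECAP threshold at or above motor threshold."""
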
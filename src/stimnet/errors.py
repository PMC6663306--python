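"""Exception types shared across the pipeline."""


class StimnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(StimnetError, ValueError):
    """A configuration value is missing, empty, or out of range."""


class NyquistError(InvalidConfigError):
    """Sampling rate too low for the requested analysis bands."""


class ScheduleError(StimnetError, ValueError):
    """A stimulation schedule is inconsistent with the recording."""


class ReferencingError(StimnetError, ValueError):
    """Re-referencing cannot be applied to this recording."""


class InsufficientDataError(StimnetError, ValueError):
    """Not enough trials / samples / sessions for the requested statistic."""


class BandResolutionError(StimnetError, ValueError):
    """A frequency band contains no spectral bins at this fs / window length."""


class AlignmentError(StimnetError, ValueError):
    """Two objects that must share a node/feature layout do not."""


class DegenerateStatisticError(StimnetError, ValueError):
    """A statistic is undefined for this input (zero variance, single class...)."""


class GenerationError(StimnetError, RuntimeError):
    """A synthetic draw failed its validity constraints after retries."""
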
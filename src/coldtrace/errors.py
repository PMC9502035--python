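"""Exception types shared across the pipeline."""


class ColdtraceError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(ColdtraceError, ValueError):
    """A parameter violates a documented precondition."""


class DegenerateImageError(ColdtraceError, ValueError):
    """Image has no contrast (constant), so no threshold exists."""


class DegenerateTraceError(ColdtraceError, ValueError):
    """A trace cannot be normalized (e.g. zero reference area or baseline)."""


class InvalidTrainError(ColdtraceError, ValueError):
    """Spike times are unsorted or fall outside the recording window."""


class InvalidSignalError(ColdtraceError, ValueError):
    """Raw electrode trace contains non-finite samples."""


class EmptyCohortError(ColdtraceError, ValueError):
    """A summary was requested for an empty cohort."""
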
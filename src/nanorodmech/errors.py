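"""Exception hierarchy shared across the package."""


class NanorodError(Exception):
    """Base class for all package errors."""


class ParameterError(NanorodError, ValueError):
    """An argument violates a documented precondition."""


class EmptyEnsembleError(NanorodError):
    """A filtering or loading step produced an ensemble with no fibers."""


class ModeError(NanorodError):
    """A profile was passed to a fit that expects a different profile mode."""


class FitError(NanorodError, RuntimeError):
    """A least-squares fit failed to converge or produced a degenerate result."""


class AnalysisError(NanorodError):
    """A derived quantity cannot be computed from the given curve or window."""


class ParseError(NanorodError, ValueError):
    """A text input file could not be parsed; message carries the line number."""
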
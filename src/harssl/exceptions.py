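"""Package exception hierarchy."""


class HarSSLError(Exception):
    """Base class for all harssl errors."""


class InvalidInputError(HarSSLError, ValueError):
    """Raised when an operation receives input violating its preconditions."""


class ConfigError(HarSSLError, ValueError):
    """Raised for invalid or incomplete configuration."""


class DegenerateDataError(HarSSLError, ValueError):
    """Raised when data are too degenerate for the requested operation
    (e.g. PCA on a rank-deficient feature set)."""


class NotTrainedError(HarSSLError, RuntimeError):
    """Raised when a fitted object is required but none is available."""


class ParseError(HarSSLError, ValueError):
    """Raised when an input file cannot be parsed; carries line context."""


class AlignmentError(HarSSLError, ValueError):
    """Raised when per-run metric histories cannot be aligned cycle-by-cycle."""
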
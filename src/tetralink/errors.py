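"""Exception hierarchy shared by all pipeline stages."""


class TetralinkError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(TetralinkError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(TetralinkError):
    """A malformed input file; the message carries the line number."""


class ValidationError(TetralinkError):
    """A well-formed row or value that violates a domain invariant."""


class ConsistencyError(TetralinkError):
    """Cross-table inconsistency (e.g. a scaffold claimed by two bins)."""


class InsufficientDataError(TetralinkError):
    """Not enough observations to compute the requested statistic."""
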
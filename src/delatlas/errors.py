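"""Package-wide exception types."""


class DelatlasError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(DelatlasError, ValueError):
    """A generator or pipeline configuration violates its invariants."""


class InvalidArgumentError(DelatlasError, ValueError):
    """An operation received an out-of-range or inconsistent argument."""


class InvalidPartitionError(DelatlasError, ValueError):
    """A domain partition is unusable for the requested operation."""


class EmptyOutputError(DelatlasError, ValueError):
    """An operation would return an empty result (e.g. all rows dropped)."""


class ParseError(DelatlasError, ValueError):
    """A file could not be parsed; message names the offending row/column."""
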
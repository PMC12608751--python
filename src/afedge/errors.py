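"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`AfEdgeError`; the CLI maps these
onto stable exit codes (validation 2, I/O 3, degenerate data 4).
"""


class AfEdgeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(AfEdgeError):
    """Malformed arguments, shapes, labels or file contents."""

    exit_code = 2


class ConfigError(ValidationError):
    """A configuration object violates its invariants."""


class EmptyInputError(ValidationError):
    """Input has too few elements to define any output (e.g. < 2 R-peaks)."""


class TooShortError(ValidationError):
    """Sequence shorter than one window; raised instead of returning an empty set."""


class SplitError(ValidationError):
    """A train/test partition cannot be formed (fewer than 2 windows)."""


class InputOutputError(AfEdgeError):
    """Missing or unreadable file; message names the path."""

    exit_code = 3


class DegenerateDataError(AfEdgeError):
    """Training data contains a single class."""

    exit_code = 4


class CorruptBundleError(AfEdgeError):
    """Weight bundle failed checksum or shape verification on load."""

    exit_code = 3
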
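"""Exception hierarchy shared across the pipeline.

``ValidationError`` covers malformed inputs (bad files, broken invariants on
in-memory objects); ``ConfigurationError`` covers bad parameter combinations
and missing contrasts.  Both map to exit code 1 in the CLI; anything else is a
runtime error (exit code 2).
"""


class SecretopanelError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(SecretopanelError, ValueError):
    """Input data violates a documented invariant."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending cell."""


class ConfigurationError(SecretopanelError, ValueError):
    """A parameter set or requested operation is inconsistent."""


class UsageError(SecretopanelError, TypeError):
    """An operation was applied to an object of the wrong kind."""
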
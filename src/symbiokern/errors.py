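"""Exception hierarchy.

Exit-code convention for the CLI: 0 ok, 1 validation failure, 2 runtime error.
"""


class SymbiokernError(Exception):
    """Base class for all package errors."""

    exit_code = 2


class ArgumentError(SymbiokernError, ValueError):
    """An argument is outside its documented domain."""


class ValidationError(SymbiokernError):
    """Input data failed validation (bad values, malformed files)."""

    exit_code = 1


class ConsistencyError(ValidationError):
    """Cross-table consistency violated (e.g. design references a missing array)."""


class PreconditionError(SymbiokernError):
    """An operation's stated precondition does not hold."""


class DegenerateDataError(SymbiokernError):
    """Data carry no usable information for the requested estimate."""


class FixtureError(ValidationError):
    """A packaged fixture failed its self-checks."""
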
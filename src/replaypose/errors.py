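"""Exception hierarchy.

Exit codes used by the CLI: 0 success, 2 validation, 3 I/O, 4 numeric or
propagation failure.
"""


class ReplayPoseError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(ReplayPoseError):
    """Invalid configuration value, parameter, or precondition."""

    exit_code = 2


class SelectionError(ValidationError):
    """Atom-selection expression resolved to zero atoms or is ambiguous."""


class ConsistencyError(ValidationError):
    """Inputs that must agree (atom counts, label lengths) do not."""


class InputError(ReplayPoseError):
    """Unreadable or unwritable file."""

    exit_code = 3


class FormatError(InputError):
    """File parsed but violates the expected format (e.g. zero atoms)."""


class NumericError(ReplayPoseError):
    """Non-finite or non-convergent numerical result."""

    exit_code = 4


class PropagationError(NumericError):
    """A propagation segment failed; carries the offending state tag."""

    def __init__(self, message: str, tag: str | None = None):
        super().__init__(message)
        self.tag = tag
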
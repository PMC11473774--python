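"""Exception hierarchy shared across the package.

``ValidationError`` signals malformed inputs (CLI exit code 2);
``PreconditionError`` signals inputs that are well-formed but violate an
operation's preconditions (CLI exit code 3).
"""


class IrisError(Exception):
    """Base class for all package errors."""


class ValidationError(IrisError):
    """Malformed or inconsistent input data / configuration."""


class PreconditionError(IrisError):
    """A well-formed input that violates an operation precondition."""
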
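"""Exception hierarchy shared across the package.

``ValidationError`` signals malformed user input (bad files, bad
parameters); ``StageError`` signals a failure inside a pipeline stage
after its inputs were accepted.  The CLI maps them to exit codes 2 and 3.
"""


class HealthexpError(Exception):
    """Base class for all package errors."""


class ValidationError(HealthexpError, ValueError):
    """Invalid input data or configuration."""


class StageError(HealthexpError, RuntimeError):
    """A pipeline stage failed on valid inputs."""
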
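"""Exception hierarchy shared across the package.

``InputError`` maps to CLI exit code 1, ``RuntimeFailure`` to exit code 2.
"""


class PeriometError(Exception):
    """Base class for all package-specific errors."""


class InputError(PeriometError, ValueError):
    """Invalid user-supplied input (bad mask, wrong shape, unknown option)."""


class ConfigurationError(InputError):
    """Degenerate or inconsistent configuration (e.g. min > max range)."""


class GeometryError(InputError):
    """Scene or mask geometry violates a required invariant."""


class EmptyMaskError(InputError):
    """An operation that requires foreground pixels received an empty mask."""


class RuntimeFailure(PeriometError, RuntimeError):
    """Unrecoverable failure during processing (e.g. non-finite loss)."""


class TrainingError(RuntimeFailure):
    """Training diverged; carries the epoch index where it happened."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
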
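"""Exception hierarchy shared by all pipeline stages."""


class AxskelError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(AxskelError, ValueError):
    """A caller-supplied argument violates a precondition."""


class EmptyMaskError(AxskelError, ValueError):
    """An operation requiring a non-empty mask received an empty one."""


class MissingStructureError(AxskelError, KeyError):
    """A required anatomical structure is absent from a label volume."""


class GenerationError(AxskelError, RuntimeError):
    """Phantom construction produced overlapping bone structures."""


class RegistrationError(AxskelError, RuntimeError):
    """Image registration failed or received degenerate input."""


class UndefinedMetricError(AxskelError, ValueError):
    """A metric is undefined for the given input (e.g. empty mask, one-class ROC)."""
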
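"""Exception hierarchy shared by all mammotex modules."""


class MammotexError(Exception):
    """Base class for all package errors."""


class ParameterError(MammotexError, ValueError):
    """Invalid user-supplied parameter (dimensions, contrast, counts ...)."""


class InputError(MammotexError, ValueError):
    """Invalid runtime input (shape/channel mismatch, image too small ...)."""


class ConfigError(MammotexError, ValueError):
    """Malformed network or pipeline configuration."""


class StructuralError(MammotexError, ValueError):
    """Mismatched structures (Gram-set layers, RDM condition sets ...)."""


class CoverageError(MammotexError, ValueError):
    """A required combination was never observed (e.g. unrated image pair)."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class DegenerateDataError(MammotexError, ValueError):
    """Data formally valid but statistically degenerate (single class,
    zero-variance paired differences, missing trial class ...)."""


class NumericalFailureError(MammotexError, ArithmeticError):
    """Non-finite value encountered during optimization."""

    def __init__(self, message, iteration=None):
        super().__init__(message)
        self.iteration = iteration
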
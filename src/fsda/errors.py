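"""Exception hierarchy shared across the package."""


class FsdaError(Exception):
    """Base class for all package errors."""


class ValidationError(FsdaError, ValueError):
    """Malformed or non-finite input."""


class DegenerateClassError(ValidationError):
    """A class has too few samples for its scatter to be defined."""


class NoDiscriminantDirectionError(FsdaError):
    """Class means coincide; no discriminant direction exists."""


class IllConditionedError(FsdaError):
    """A linear system involved in the fit is numerically singular."""


class SubspaceExhausted(FsdaError):
    """No further discriminant direction with positive value exists.

    Raised internally by the recursion; ``fit_basis`` catches it and
    truncates the basis with a warning.
    """


class EmbeddingError(FsdaError):
    """A text embedder failed on an input."""


class MissingDependencyError(FsdaError, ImportError):
    """An optional extra is required but not installed."""


class ConfigError(FsdaError, ValueError):
    """Invalid run configuration; message lists every problem found."""
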
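"""Exception hierarchy shared across the pipeline."""


class RegenPhaseError(Exception):
    """Base class for all package errors."""


class FormatError(RegenPhaseError, ValueError):
    """Malformed input table (duplicate ids, negative or non-integer counts...)."""


class ConsistencyError(RegenPhaseError, ValueError):
    """Two inputs that must agree (gene ids, sample ids) do not."""


class EmptySelectionError(RegenPhaseError, ValueError):
    """A selection (structure, gene set...) matched nothing."""


class ParameterError(RegenPhaseError, ValueError):
    """An argument is outside its valid range."""


class GeometryError(RegenPhaseError, ValueError):
    """Degenerate geometric input (too few vertices, coincident points)."""


class ConfigError(RegenPhaseError, ValueError):
    """Invalid configuration values."""
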
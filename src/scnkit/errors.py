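"""Exception types shared across the package."""


class ScnkitError(Exception):
    """Base class for all package errors."""


class SchemaError(ScnkitError, ValueError):
    """A table is missing a mandatory column or violates its schema."""


class DimensionError(ScnkitError, ValueError):
    """An array or table has the wrong shape for the requested operation."""


class StructuralInputError(ScnkitError, ValueError):
    """A graph/matrix input violates a structural precondition
    (e.g. an adjacency matrix that is not symmetric and hollow)."""


class ConfigError(ScnkitError, ValueError):
    """A configuration value is invalid or inconsistent."""
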
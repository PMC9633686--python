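"""Exception hierarchy shared across the package."""


class FopLabelError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FopLabelError):
    """An input table does not match the expected column schema."""


class ValidationError(FopLabelError):
    """A record violates a domain invariant (names row/field where known)."""


class ConfigError(FopLabelError):
    """A configuration file or object is malformed."""


class JoinError(FopLabelError):
    """Identifiers in one table have no match in another."""


class StateError(FopLabelError):
    """Solid and liquid items were mixed where a single state is required."""


class FitError(FopLabelError):
    """A survival-model fit could not be carried out."""
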
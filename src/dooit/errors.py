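"""Exception hierarchy for the DOO-IT toolkit."""


class DooItError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DooItError):
    """A required column is missing or the schema file is malformed."""


class ParseError(DooItError):
    """A cell could not be parsed as a number; carries row/column coordinates."""


class CompositionError(DooItError):
    """Solvent mole fractions violate the sum-to-one constraint."""


class DegenerateInputError(DooItError):
    """Input too small or too uniform for the requested operation."""


class DegenerateGeometryError(DooItError):
    """All pairwise distances in the sampled subset are zero."""


class DegenerateFitError(DooItError):
    """A model interpolated the training data (RSS <= 0); it cannot be scored."""


class FitError(DooItError):
    """The SVR solver failed; carries the hyperparameters and feature subset."""


class ConfigurationError(DooItError):
    """Inconsistent search or cross-validation configuration."""


class LeakageError(DooItError):
    """Held-out test rows participated in model selection."""


class IterationError(DooItError):
    """A pruning iteration failed entirely; carries a failure log."""
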
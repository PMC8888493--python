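"""Exception hierarchy shared across the package."""


class NutriscapeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NutriscapeError, ValueError):
    """Invalid argument values (negative parts, empty lists, bad alpha ...)."""


class ConfigurationError(NutriscapeError):
    """Missing or inconsistent simulation / analysis configuration."""


class SchemaError(NutriscapeError):
    """Input table does not match the expected column schema."""


class ParseError(NutriscapeError):
    """A row of an input table could not be parsed; carries its location."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DesignError(NutriscapeError):
    """Rank-deficient or otherwise unusable regression design."""


class DegenerateScaleError(NutriscapeError, ValueError):
    """Standardization requested for a constant (zero-variance) variable."""


class ExcludedRecordError(NutriscapeError):
    """Signals an individual with no reproductive assays (excluded from analysis)."""
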
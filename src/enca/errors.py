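"""Exception hierarchy for the accounting engine."""


class EncaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EncaError):
    """Invalid scene or run configuration."""


class ScenarioError(EncaError):
    """A change scenario requests more pixels than a class can supply."""


class AlignmentError(EncaError):
    """Rasters are not co-registered (shape or grid mismatch)."""


class NomenclatureError(EncaError):
    """A raster contains a class code outside the declared palette."""


class SchemaError(EncaError):
    """A mandatory account line item is missing for a SELU."""


class ParameterError(EncaError):
    """A per-class parameter (density, weight, ...) is missing or invalid."""


class DomainError(EncaError):
    """An index or ratio argument is outside its admissible range."""


class DataError(EncaError):
    """Invalid input data (e.g. non-positive river discharge)."""
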
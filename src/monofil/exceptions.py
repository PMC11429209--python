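"""Exception and warning types shared across the package."""


class MonofilError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MonofilError, ValueError):
    """An input is outside the physical or mathematical domain of an operation."""


class ConfigurationError(MonofilError, ValueError):
    """A required configuration value (coefficient, key) is missing or invalid."""


class OverloadError(MonofilError, ValueError):
    """A force exceeds the instrument's 500 gf admissible load."""


class GenerationError(MonofilError, ValueError):
    """A synthetic-data spec cannot produce a well-formed output."""


class CsvFormatError(MonofilError, ValueError):
    """A CSV input does not conform to the declared dialect."""


class EulerSlendernessWarning(UserWarning):
    """Column slenderness is low enough that Euler buckling theory is marginal."""


class NoBucklingWarning(UserWarning):
    """A force-displacement curve shows no slope drop; no buckling detected."""
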
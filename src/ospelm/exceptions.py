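"""Exception hierarchy shared across the package."""


class OSPELMError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OSPELMError, ValueError):
    """An input lies outside the physical/mathematical domain of an operation."""


class ConfigurationError(OSPELMError, ValueError):
    """A configuration value or combination of values is invalid."""


class NumericError(OSPELMError, ArithmeticError):
    """A numerical computation produced non-finite or singular results."""


class ParseError(OSPELMError, ValueError):
    """A dataset file could not be parsed; message names the row/column."""


class ModelFormatError(OSPELMError, ValueError):
    """A model file is corrupted or has an incompatible version."""
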
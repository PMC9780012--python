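"""Exception hierarchy shared across the package."""


class PhysiostateError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhysiostateError, ValueError):
    """A configuration value is invalid or inconsistent."""


class DataFormatError(PhysiostateError, ValueError):
    """An input file or table violates the expected layout."""


class InvalidOffsetError(PhysiostateError, ValueError):
    """Coarse-graining offset k outside 1..tau."""


class ScaleTooLargeError(PhysiostateError, ValueError):
    """Scale factor tau exceeds the series length."""


class TooShortError(PhysiostateError, ValueError):
    """Series too short for the requested embedding dimension."""
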
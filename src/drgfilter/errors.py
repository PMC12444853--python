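"""Exception hierarchy used across the package."""


class DrgFilterError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DrgFilterError):
    """A file's contents violate the expected on-disk layout."""


class MetadataError(DrgFilterError):
    """Required acquisition metadata is missing or inconsistent."""


class ParameterError(DrgFilterError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class DegenerateSignalError(DrgFilterError):
    """The signal carries no usable variability (e.g. MAD = 0)."""


class DegenerateRegressorError(DrgFilterError):
    """A regressor has zero variance and cannot be fit against."""


class InsufficientDataError(DrgFilterError):
    """Too few observations for the requested computation."""


class DomainError(DrgFilterError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""
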
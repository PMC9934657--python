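"""Exception hierarchy shared across the package."""


class CsakitError(Exception):
    """Base class for all package errors."""


class InputError(CsakitError):
    """A required input is missing, empty, or unusable."""


class FormatError(CsakitError):
    """An input file or table does not follow its documented schema."""


class ContractError(CsakitError):
    """An internal pre-condition was violated by the caller."""


class TooShortError(CsakitError):
    """A chromatogram has too few points to be smoothed or correlated."""


class ValidationError(CsakitError):
    """A configuration value is unknown or out of its documented range."""
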
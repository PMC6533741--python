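"""Exception hierarchy shared across the package."""


class CleftminerError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CleftminerError):
    """A file did not conform to the expected dialect (missing column, bad row)."""


class EmptyInputError(CleftminerError):
    """An input that must be non-empty was empty."""


class DomainError(CleftminerError, ValueError):
    """A numeric argument violated its documented bounds."""


class LookupFailure(CleftminerError, KeyError):
    """A requested identifier does not exist in the container."""


class UninformativeSNP(CleftminerError):
    """Raised when a SNP has no informative transmissions (b + c == 0)."""
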
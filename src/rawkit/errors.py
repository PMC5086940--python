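"""Exception hierarchy shared across the package."""


class RawkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RawkitError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(RawkitError):
    """Parsed content violates a domain invariant (bounds, uniqueness, sign)."""


class CoverageError(RawkitError):
    """An intensity table covers too small a fraction of the annotation."""


class ConfigurationError(RawkitError):
    """Inputs are structurally valid but insufficient for the requested fit."""
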
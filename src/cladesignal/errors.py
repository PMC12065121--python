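"""Exception hierarchy shared across the package."""


class CladeSignalError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(CladeSignalError):
    """Raised when a Newick string cannot be parsed."""


class ValidationError(CladeSignalError):
    """Raised when an input violates a structural invariant."""


class CurationError(CladeSignalError):
    """Raised when metadata curation cannot proceed (e.g. empty result)."""
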
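"""Exception hierarchy shared across the package."""


class SomnoscoreError(Exception):
    """Base class for all package errors."""


class FormatError(SomnoscoreError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(SomnoscoreError):
    """Well-formed input that violates a domain invariant."""
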
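"""Exception types raised across the package."""


class DoeeError(Exception):
    """Base class for all package errors."""


class ValidationError(DoeeError):
    """Input data violates a structural requirement (non-binary mask,
    degenerate polygon, out-of-bounds vertex, ...)."""


class PairingError(DoeeError):
    """Two rater inputs cannot be paired (shape mismatch, missing file)."""


class SchemaError(DoeeError):
    """A serialized contour set is malformed; the message names the field."""


class DegenerateScanError(DoeeError):
    """Both raters drew nothing: MTA = 0 and the agreement indices are
    undefined."""


class InsufficientDataError(DoeeError):
    """Too few scans to fit the requested models."""


class DomainError(DoeeError):
    """A numeric argument lies outside the domain of the requested
    quantity (e.g. MTA <= 0 for the similarity estimate)."""
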
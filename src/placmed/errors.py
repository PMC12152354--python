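"""Typed error hierarchy.

Every invariant violation raises one of these; messages name the offending
record(s) so failures are actionable. CLI maps ``ConfigError``/``ValidationError``
subclasses to exit code 2 and everything else to 3.
"""


class PlacmedError(Exception):
    """Base class for all package errors."""


class FormatError(PlacmedError):
    """A file does not conform to its declared on-disk format."""


class SchemaError(PlacmedError):
    """A table is missing required columns or has wrong dtypes."""


class ValidationError(PlacmedError):
    """Data violates a domain invariant (dimensions, ranges, duplicates)."""


class ConfigError(PlacmedError):
    """Invalid simulation or pipeline configuration."""


class EmptyResultError(PlacmedError):
    """An operation removed every record; message carries per-criterion counts."""


class DesignMatrixError(PlacmedError):
    """Rank-deficient or otherwise unusable regression design."""


class DegenerateModelError(PlacmedError):
    """A requested quantity is undefined for the fitted/true model."""
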
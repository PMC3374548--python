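"""Exception hierarchy shared across the package."""


class AwagError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AwagError):
    """Input file does not match the declared attribute schema."""


class ValidationError(AwagError):
    """A record violates a data-model invariant (e.g. non-binary stage)."""


class UnknownNameError(AwagError, LookupError):
    """An unknown variable, service, or fixture name was requested."""


class DegenerateInputError(AwagError):
    """An operation received an empty or otherwise degenerate subset."""


class UnsupportedInputError(AwagError):
    """The operation requires counts (or respondent-level data) not present."""


class UndefinedGapError(AwagError):
    """Gap ratio requested with a zero reference rate."""


class FeasibilityError(AwagError):
    """Requested marginal rates are not jointly attainable."""


class InvalidRegionError(AwagError, KeyError):
    """(category, subcategory) pair does not exist in the segment matrix."""
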
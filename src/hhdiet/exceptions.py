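"""Exception hierarchy for the pipeline.

Every error raised deliberately by this package derives from :class:`HHDietError`
so callers can catch pipeline failures without masking programming errors.
"""


class HHDietError(Exception):
    """Base class for all errors raised by hhdiet."""


class SchemaError(HHDietError):
    """An input table is missing a required column or has a malformed header."""


class ReferentialError(HHDietError):
    """A row references an identifier that does not resolve in its parent table."""


class VocabularyError(HHDietError):
    """A value falls outside a closed vocabulary (region, group label, sex, ...)."""


class ValidationError(HHDietError):
    """A value violates a domain invariant (negative grams, retention > 1, ...)."""


class StratumLookupError(HHDietError):
    """A household member's (sex, age, activity) stratum is absent from the
    energy-requirement table."""


class LinkageError(HHDietError):
    """A consumed item cannot be linked to a reference table (composition or
    footprint factors)."""


class ConfigError(HHDietError):
    """The run configuration is inconsistent or incomplete."""


class DegenerateInputError(HHDietError):
    """The input data cannot support the requested computation (constant
    column, zero energy, empty stratum, ...)."""


class AlignmentError(HHDietError):
    """Two per-household inputs do not cover the same households."""
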
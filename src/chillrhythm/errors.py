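"""Exception hierarchy shared across the package."""


class ChillRhythmError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ChillRhythmError):
    """A configuration field failed validation; the message names the field."""


class SchemaError(ChillRhythmError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(ChillRhythmError):
    """Input values violate a contract (range, duplicates, sums)."""


class FormatError(ChillRhythmError):
    """A label could not be parsed (e.g. fatty acid not 'carbon:double_bonds')."""


class InsufficientDataError(ChillRhythmError):
    """Too few observations or distinct time points for the requested fit."""


class DegenerateSampleError(ChillRhythmError):
    """A sample or pool is empty/all-zero where positive mass is required."""


class AlignmentError(ChillRhythmError):
    """Two time grids could not be aligned under the requested strategy."""
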
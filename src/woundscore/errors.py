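"""Exception hierarchy for assay parsing, validation and analysis."""


class AssayError(Exception):
    """Base class for all woundscore errors."""


class FormatError(AssayError):
    """A file is structurally malformed (missing column, orphan well, bad value type)."""


class RangeError(AssayError):
    """A numeric value is outside its physically admissible range."""


class SequencingError(AssayError):
    """Time points are missing, unordered, or inconsistent between wells."""


class StratumError(AssayError):
    """A (cell line, density, MMC) stratum violates a completeness requirement."""


class WindowError(AssayError):
    """An analysis window falls outside the observed time range."""


class DegenerateControlError(AssayError):
    """The vehicle control carries no usable signal (zero closure AUC)."""


class InsufficientDataError(AssayError):
    """Too few points for the requested computation."""


class CompletenessError(AssayError):
    """A matrix input has missing entries."""


class EmptyInputError(AssayError):
    """An operation received an empty collection."""
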
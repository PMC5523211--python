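"""Exception hierarchy shared across the package.

``BarcodeGapError`` is the common base; ``ValidationError`` subclasses map to
CLI exit code 2, everything else raised mid-analysis maps to exit code 3.
"""


class BarcodeGapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BarcodeGapError):
    """Invalid user input (bad file contents, bad configuration)."""


class AlignmentShapeError(ValidationError):
    """Rows of an alignment do not all have the same length."""


class AlphabetError(ValidationError):
    """A sequence contains a character outside DNA + missing symbols."""


class DuplicateIdError(ValidationError):
    """The same sequence id occurs more than once."""


class SchemaError(ValidationError):
    """A metadata table is missing required columns."""


class BindingError(ValidationError):
    """FASTA ids and metadata ids cannot be reconciled in strict mode."""


class ConfigError(ValidationError):
    """An invalid simulation or run configuration."""


class IncompleteMatrixError(BarcodeGapError):
    """A distance matrix contains undefined (zero-overlap) entries where a
    complete matrix is required."""


class DegenerateDataError(BarcodeGapError):
    """Bootstrap resampling kept producing matrices with undefined entries."""


class SummaryError(BarcodeGapError):
    """All pairwise distances for a species are undefined."""


class StageError(BarcodeGapError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
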
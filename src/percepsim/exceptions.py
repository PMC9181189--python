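"""Exception hierarchy for percepsim.

Every error raised deliberately by the package derives from
:class:`PercepsimError`, so callers (and the CLI) can catch one type.
"""


class PercepsimError(Exception):
    """Base class for all percepsim errors."""


class SmilesParseError(PercepsimError):
    """A SMILES string could not be parsed; the message names the string."""


class StandardizationError(PercepsimError):
    """Standardization produced an empty or invalid structure."""


class SchemaError(PercepsimError):
    """A tabular file does not match any registered schema."""


class TableValidationError(PercepsimError):
    """Rows of a pair/vote table violate domain invariants."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class ModelFormatError(PercepsimError):
    """A model file is malformed, incomplete, or has an unsupported version."""


class FeatureError(PercepsimError):
    """Required similarity features are missing or out of domain."""


class NoThresholdError(PercepsimError):
    """Threshold inversion is impossible (zero feature coefficient)."""


class ConformerGenerationError(PercepsimError):
    """3D embedding failed for a molecule; the message names it."""


class SelectionError(PercepsimError):
    """A stratified selection quota cannot be met; names the subset."""


class PoolGenerationError(PercepsimError):
    """Synthetic pair-pool generation starved before filling a quota."""


class EvaluationError(PercepsimError):
    """Predictions and truth cannot be compared (length/label problems)."""
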
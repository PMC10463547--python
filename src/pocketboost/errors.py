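"""Exception hierarchy shared across the package."""


class PocketboostError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(PocketboostError):
    """A structure file contained no parsable residues."""


class FormatError(PocketboostError):
    """A text file does not conform to its declared format."""


class SchemaError(PocketboostError):
    """Tabular input or a feature vector does not match the expected schema."""


class StructureError(PocketboostError):
    """A ligand structure could not be parsed at all."""

    def __init__(self, message: str, payload: object | None = None):
        super().__init__(message)
        self.payload = payload


class StandardizationError(PocketboostError):
    """Every enabled standardization stage failed.

    ``stage_messages`` maps stage name to the failure message it produced.
    """

    def __init__(self, stage_messages: dict[str, str]):
        self.stage_messages = dict(stage_messages)
        detail = "; ".join(f"{k}: {v}" for k, v in self.stage_messages.items())
        super().__init__(f"all standardization stages failed ({detail})")


class FeatureError(PocketboostError):
    """A descriptor could not be computed on an otherwise valid molecule."""


class DataError(PocketboostError):
    """Model input contains values the learner cannot consume."""


class UndefinedCorrelationError(PocketboostError):
    """Pearson correlation requested on a zero-variance vector."""
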
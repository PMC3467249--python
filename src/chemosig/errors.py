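"""Exception hierarchy shared across the pipeline stages."""


class ChemosigError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ChemosigError):
    """A file is structurally malformed (e.g. a required column is absent)."""


class ParseError(ChemosigError):
    """A cell could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"{message} (line {line})")
        self.line = line


class VocabularyError(ChemosigError):
    """A value falls outside a closed vocabulary."""


class IntegrityError(ChemosigError):
    """Duplicate keys or inconsistent cross-references within a table."""


class ValidationError(ChemosigError):
    """A value violates a domain invariant (range, sign, ...)."""


class EmptyArrayError(ChemosigError):
    """No usable spots remain after filtering."""


class ParameterError(ChemosigError):
    """An algorithm parameter is outside its admissible range."""


class JoinError(ChemosigError):
    """Tables that must be joined do not align."""


class DegenerateLabelError(ChemosigError):
    """A classifier was handed a single-class label vector."""


class SizeError(ChemosigError):
    """A requested size exceeds what is available."""


class EncodingError(ChemosigError):
    """A covariate cannot be encoded as requested."""


class StateError(ChemosigError):
    """An operation was called before its required state existed."""


class DimensionError(ChemosigError):
    """An embedding dimension is incompatible with the number of points."""


class DomainError(ChemosigError):
    """An input value is outside the mathematical domain of an operation."""
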
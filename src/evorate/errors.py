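"""Typed errors raised by the pipeline stages."""


class EvorateError(Exception):
    """Base class for all pipeline errors."""


class ParseError(EvorateError):
    """Input file could not be parsed in the stated format."""


class UnequalLengthError(ParseError):
    """Alignment records differ in length."""


class QueryMissingError(EvorateError):
    """The query id is absent from the alignment (or sequence set)."""


class EmptyAlignmentError(EvorateError):
    """No usable (non-gap) characters found."""


class TooFewHomologuesError(EvorateError):
    """Fewer homologues (including the query) than the hard minimum."""


class DegenerateInputError(EvorateError):
    """Input too small for the requested operation (e.g. < 2 taxa)."""


class LabelMismatchError(EvorateError):
    """Tree leaf labels and alignment taxa disagree."""


class QueryOutsideSubtreeError(EvorateError):
    """The selected clade does not contain the query leaf."""


class InvalidGradeError(EvorateError):
    """Conservation grade outside 1..9."""


class UnknownChainError(EvorateError):
    """Requested chain id not present in the structure."""


class EmptyStructureError(EvorateError):
    """Structure contains no polymer residues."""


class MappingError(EvorateError):
    """Query and chain sequences are too dissimilar to be the same molecule."""


class ExternalToolNotFoundError(EvorateError):
    """A configured external executable is not on PATH."""


class MissingSequenceError(EvorateError):
    """A hit-table entry has no sequence available."""
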
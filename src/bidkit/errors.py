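"""Exception hierarchy for bidkit."""


class BidkitError(Exception):
    """Base class for all bidkit errors."""


class FormatError(BidkitError):
    """A file could not be parsed in the expected format."""


class RoleError(BidkitError):
    """Chain-role annotations are missing or inconsistent."""


class AlignmentError(BidkitError):
    """An alignment is ragged or otherwise malformed."""


class ConsistencyError(BidkitError):
    """Cross-referenced records disagree (masks, rows, members)."""


class AnnotationError(BidkitError):
    """Epitope annotation preconditions are violated."""


class EmbeddingError(BidkitError):
    """An embedding matrix does not match the chain it describes."""


class ModelError(BidkitError):
    """Model parameters are incompatible with the given input."""


class SplitError(BidkitError):
    """A profile violates the train/test depth invariants."""


class AnalysisError(BidkitError):
    """Statistical analysis preconditions are violated."""
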
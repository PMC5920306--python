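"""Exception hierarchy for the florphen pipeline."""


class FlorphenError(Exception):
    """Base class for all florphen-specific errors."""


class AlignmentShapeError(FlorphenError):
    """Sequences or consensus strings are not all of equal length."""


class AnnotationError(FlorphenError):
    """Annotation table is malformed, incomplete, or uses unknown tokens."""


class DuplicateIdError(FlorphenError):
    """The same sequence identifier occurs more than once."""


class CurationEmptyError(FlorphenError):
    """Curation removed every column; parameters are too strict."""


class GroupTooSmallError(FlorphenError):
    """A functional group has fewer than two member sequences."""


class EmptyUniqueSetError(FlorphenError):
    """A unique-position set holds no positions to match against."""


class NoScorableColumnsError(FlorphenError):
    """A query has no column at which a prevalence score can be taken."""


class DivisionByZeroScoreError(FlorphenError):
    """Out-group score is zero; the ratio is undefined (degenerate out-group)."""


class CalibrationImpossibleError(FlorphenError):
    """Every member ratio lies below every non-member ratio."""


class SampleMismatchError(FlorphenError):
    """Samples or sample sets do not line up between inputs."""


class EmptyGroupError(FlorphenError):
    """A biological-replicate group is empty."""


class MissingEventError(FlorphenError):
    """A phenology record lacks a required event day."""


class DataConsistencyError(FlorphenError):
    """Internally inconsistent record (e.g. fruit weight without fruits)."""


class ParamError(FlorphenError):
    """Simulation parameters are inconsistent or out of range."""


class ConfigError(FlorphenError):
    """Pipeline configuration violates its schema."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")
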
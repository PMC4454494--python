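"""Exception hierarchy for matrix validation and pipeline failures."""


class MorphodispError(Exception):
    """Base class for all package errors."""


class ValidationError(MorphodispError):
    """Invalid input data (matrix, spec, or group file)."""


class DuplicateTaxonError(ValidationError):
    """A taxon identifier appears more than once."""


class InvalidStateError(ValidationError):
    """A cell holds a state not admissible under its character spec."""


class SpecMismatchError(ValidationError):
    """Matrix columns do not match the character specification."""


class UnknownTaxonError(ValidationError):
    """A group file references a taxon absent from the matrix."""


class EmptyColumnError(ValidationError):
    """A character column has no observed (non-missing) values."""


class NoComparableCharactersError(MorphodispError):
    """A taxon pair shares no comparable (jointly observed) character."""


class DegenerateAxisError(MorphodispError):
    """An ordination axis is constant and cannot be binned."""


class ContinuousCharacterError(MorphodispError):
    """A numeric character has non-discrete observed values and cannot be
    cross-tabulated."""


class PipelineStageError(MorphodispError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
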
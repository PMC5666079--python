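"""Exception hierarchy. Usage errors subclass ValueError so callers can catch broadly."""


class MtleoError(Exception):
    """Base class for all package errors."""


class DataValidationError(MtleoError, ValueError):
    """Malformed or inconsistent input data."""


class UnknownResidueError(DataValidationError):
    """A residue with no hydropathy-scale entry and no non-standard policy."""


class WindowError(DataValidationError):
    """Invalid moving-average window (even, non-positive, or longer than the sequence)."""


class MissingSubunitError(DataValidationError):
    """A species lacks one or more subunits required by the analysis set."""


class NoSelectedSitesError(DataValidationError):
    """Hydrophobic-site selection came back empty; threshold/window need revisiting."""


class SingularMassError(DataValidationError):
    """Body mass of exactly 1 in the working unit makes ln(M)=0; B is undefined."""


class SpeciesMismatchError(DataValidationError):
    """Trait, AAV and weight tables do not cover the same species set."""


class CollinearityError(DataValidationError):
    """The AAV design matrix is (numerically) rank deficient."""


class InfeasibleTargetError(DataValidationError):
    """A requested synthetic AAV target violates a feasibility bound."""


class PipelineStageError(MtleoError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
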
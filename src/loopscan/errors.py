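"""Exception hierarchy shared across the package."""


class LoopscanError(Exception):
    """Base class for all package errors."""


class PDBParseError(LoopscanError):
    """A malformed record in a PDB file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StructureError(LoopscanError):
    """Frames of a multi-model file disagree structurally."""


class SelectionError(LoopscanError):
    """A selection expression is invalid or resolves to no atoms."""


class AlignmentError(LoopscanError):
    """A domain alignment violates the triplet-map contract."""


class TripletLookupError(LoopscanError, LookupError):
    """Residue or triplet outside the aligned span."""


class MotifSyntaxError(LoopscanError):
    """A motif pattern string cannot be compiled."""


class MotifScanError(LoopscanError):
    """A sequence contains letters outside the standard alphabet."""


class DerivationError(LoopscanError):
    """Structural-element derivation is missing required motif anchors."""


class ScenarioError(LoopscanError):
    """A synthetic-data scenario violates its invariants."""


class PipelineError(LoopscanError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
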
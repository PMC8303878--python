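"""Exception hierarchy shared across the pipeline stages."""


class ValidationError(ValueError):
    """Invalid user input or specification (CLI exit code 2)."""


class StructureMismatchError(ValidationError):
    """Two structures that must share an atom layout do not."""


class DegenerateFitError(ValueError):
    """Superposition is not well defined (< 3 atoms or collinear selection)."""


class UndefinedFncError(ValueError):
    """Fraction of native contacts requested against an empty contact set."""


class NotComputableError(ValueError):
    """A metric's required inputs (e.g. backbone dihedrals) are absent."""


class StageError(RuntimeError):
    """A pipeline stage failed after validation (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
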
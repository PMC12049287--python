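"""Exception hierarchy shared by the pipeline stages."""


class ResectFitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ResectFitError):
    """A file could not be parsed as any supported format."""


class GeometryError(ResectFitError):
    """Input geometry violates an assumption (e.g. non-uniform slice spacing)."""


class DegenerateInputError(ResectFitError):
    """Input is valid but degenerate for the requested operation."""


class ValidationError(ResectFitError):
    """A parameter or domain-type invariant is violated."""


class UnitError(ResectFitError):
    """A quantity arrived in the wrong unit for the requested operation."""


class StageError(ResectFitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
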
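"""Exception hierarchy shared across the package."""


class FdrscopeError(Exception):
    """Base class for all package errors."""


class AlignmentError(FdrscopeError):
    """Rows of unequal length, or sequences that cannot be aligned/compared."""


class EmptyInputError(FdrscopeError):
    """An input file or container held no usable records."""


class SpecError(FdrscopeError):
    """A simulation or sampler specification is internally inconsistent."""


class DomainError(FdrscopeError):
    """Arguments outside the mathematical domain of an operation."""


class EmptyStructureError(FdrscopeError):
    """A structure file contained no ATOM records."""


class DegenerateGeometryError(FdrscopeError):
    """Too few or collinear points for a rigid superposition."""


class PipelineError(FdrscopeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
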
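"""Exception hierarchy shared across the package."""


class ExploraError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ExploraError, ValueError):
    """A parameter is outside its documented domain."""


class SingularMatrixError(ExploraError, ValueError):
    """Interaction matrix is singular or too ill-conditioned to invert."""


class StructuralError(ExploraError, ValueError):
    """A network lacks the structure required by an operation."""


class NotApplicableError(ExploraError, RuntimeError):
    """The requested quantity is undefined for this realization."""
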
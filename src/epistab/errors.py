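"""Exception hierarchy shared by all pipeline stages."""


class EpistabError(Exception):
    """Base class for all package errors."""


class FormatError(EpistabError):
    """A file does not conform to the expected tabular/structural format."""


class ValidationError(EpistabError):
    """Input violates a domain invariant (ordering, ranges, completeness)."""


class InsufficientDataError(ValidationError):
    """Too few points to fit the requested model."""


class StructuralError(EpistabError):
    """Trajectory frames are mutually inconsistent (atom counts, maps)."""


class FitError(EpistabError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
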
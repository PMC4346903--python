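"""Exception hierarchy for protospec.

Every error raised on purpose by the package derives from
:class:`ProtospecError`, so callers can catch one type at a pipeline
boundary while still distinguishing failure modes below it.
"""


class ProtospecError(Exception):
    """Base class for all protospec errors."""


class InvalidModelError(ProtospecError):
    """A protonation model violates a structural invariant."""


class InfeasibleCompositionError(ProtospecError):
    """The proton balance has no root in the admissible pH range."""


class ConfigurationError(ProtospecError):
    """An electrode or run configuration is internally inconsistent."""


class UnderdeterminedError(ProtospecError):
    """The requested refinement is not identifiable from the data given."""


class DialectError(ProtospecError):
    """A titration file mixes dialects or lacks a recognizable layout."""


class MalformedFileError(ProtospecError):
    """A data file failed to parse; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class InconsistentBreakdownError(ProtospecError):
    """Functional-group bookkeeping produced a negative pool."""


class DesignError(ProtospecError):
    """A synthetic titration design is physically unreachable."""


class FitError(ProtospecError):
    """The optimizer failed to produce a usable estimate."""
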
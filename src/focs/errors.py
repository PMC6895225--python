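"""Exception hierarchy shared across the package."""


class FocsError(Exception):
    """Base class for all package errors."""


class ParseError(FocsError):
    """A line of an input file could not be parsed."""

    def __init__(self, path, lineno, message):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ValidationError(FocsError):
    """An input object violates a structural invariant."""


class InfeasibleNullError(FocsError):
    """The tested node has more stubs than the external pool admits."""


class ImpossibleObservationError(FocsError):
    """An observed in-degree lies outside the null support.

    This can only arise from inconsistent graph/community bookkeeping,
    so it is raised loudly rather than clamped.
    """


class ParameterError(FocsError):
    """A user-supplied parameter is out of range."""
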
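"""Exception hierarchy for obseval.

All validation failures raise a subclass of :class:`ObsevalError`, which
itself subclasses ``ValueError`` so callers can catch either.
"""


class ObsevalError(ValueError):
    """Base class for all obseval-specific errors."""


class ParameterError(ObsevalError):
    """A model or generator parameter is invalid (names the offending field)."""


class ShapeError(ObsevalError):
    """A vector or matrix has the wrong dimension."""


class DomainError(ObsevalError):
    """An input lies outside the mathematical domain of an operation."""


class UnsupportedMethodError(ObsevalError):
    """The requested estimation method does not apply to these models."""


class EvaluationError(ObsevalError):
    """A user-supplied statistic returned a non-finite value."""


class FormatError(ObsevalError):
    """A file is malformed or in an unsupported format."""


class StudyError(ObsevalError):
    """A 2-AFC study config, session, or response log is inconsistent."""
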
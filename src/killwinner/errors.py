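"""Exception hierarchy for the pipeline."""


class KillWinnerError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(KillWinnerError, ValueError):
    """A function argument is outside its documented domain."""


class SchemaError(KillWinnerError, ValueError):
    """An input table violates its schema (missing columns, duplicate ids, ...)."""


class InsufficientDataError(KillWinnerError, ValueError):
    """Not enough observations to carry out the requested fit."""


class DegenerateDesignError(KillWinnerError, ValueError):
    """A regression design with no variation in the predictor."""


class UndefinedCorrelationError(KillWinnerError, ValueError):
    """Correlation requested on a zero-variance variable."""
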